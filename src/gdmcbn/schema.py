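"""Variable schema for discrete clinical cohorts.

Every variable is categorical; values are state *labels* (strings), and
a missing observation is a first-class state with the literal label
``"99"`` rather than an NA marker.  This mirrors how routinely collected
maternity data are analysed when missingness is potentially informative:
the fact that a lab value was never recorded can itself carry signal
about clinical decision-making, so it is modelled as a category instead
of being imputed or dropped.

:func:`build_gdm_schema` returns the default 62-variable schema of a
gestational-diabetes (GDM) cohort: demographics, medical and obstetric
history, diagnostic measurements, treatment choices, and maternal and
neonatal outcomes, each quantised into a small number of clinically
meaningful levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["VariableSpec", "MISSING", "build_gdm_schema", "schema_to_dict", "schema_from_dict"]

MISSING = "99"

_ROLES = {"demographic", "history", "diagnostic", "treatment", "outcome"}


@dataclass(frozen=True)
class VariableSpec:
    """A categorical variable: name, ordered state labels, role tag.

    ``quantisation`` optionally records how raw values map onto state
    labels (e.g. BMI intervals onto the four BMI classes); it is
    documentation carried alongside the schema, not applied by this
    package.
    """

    name: str
    states: tuple[str, ...]
    role: str = "diagnostic"
    quantisation: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError(f"{self.name}: needs >=2 states, got {self.states}")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name}: duplicate state labels in {self.states}")
        if self.role not in _ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")

    @property
    def can_be_missing(self) -> bool:
        return MISSING in self.states

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def index_of(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"{label!r} is not a state of {self.name} {self.states}") from None


def _v(name: str, states: list[str], role: str, quant: dict[str, str] | None = None) -> VariableSpec:
    return VariableSpec(name, tuple(states), role, quant or {})


def _binary(name: str, role: str) -> VariableSpec:
    return _v(name, ["0", "1", MISSING], role, {"No": "0", "Yes": "1", "Missing": MISSING})


def build_gdm_schema() -> list[VariableSpec]:
    """The default 62-variable GDM cohort schema.

    State codes follow the cohort's quantisation conventions, e.g. BMI
    Category: Underweight=1, Healthy=2, Overweight=3, Obese=4,
    Missing/Other=99; Parity: Nulliparity=0, Low Multiparity (1-2
    previous pregnancies)=1, Grand Multiparity (>=3)=2.  Yes/No
    variables use No=0, Yes=1.  The exact node-level expansion of some
    grouped source fields (delivery mode, insulin regimen, postnatal
    glucose tests) is a reconstruction and can be replaced by supplying
    a custom schema.
    """
    m = MISSING
    specs = [
        # demographics
        _v("Age", ["1", "2", "3", m], "demographic",
           {"<=24y": "1", "25-34y": "2", ">=35y": "3"}),
        _v("Ethnicity", ["1", "2", "3", "4", "5", m], "demographic",
           {"Irish/Irish Traveller": "1", "White": "2", "Black/African": "3",
            "Asian": "4", "Other": "5"}),
        _v("Occupation", ["1", "2", "3", "4", "5", "6", m], "demographic"),
        _v("Marital_Status", ["1", "2", "3", m], "demographic",
           {"Married": "1", "Single": "2", "Separated/Widowed/Divorced": "3"}),
        _v("Patient_Type", ["0", "1", m], "demographic", {"Public": "0", "Private": "1"}),
        # history
        _binary("Medical_History", "history"),
        _binary("Diabetes", "history"),
        _binary("Thyroid", "history"),
        _binary("Hypertension", "history"),
        _binary("Depression", "history"),
        _binary("Previous_Bariatric_Surgery", "history"),
        _v("Smoking", ["0", "1", "2", "3", m], "history",
           {"Never": "0", "During pregnancy": "1", "Before pregnancy": "2", "Former": "3"}),
        _v("No_of_Cigarettes_per_day", ["0", "1", "2", m], "history",
           {"None": "0", "1-10": "1", ">10": "2"}),
        _v("Alcohol", ["0", "1", "2", m], "history",
           {"None": "0", "Drinking in pregnancy": "1", "Not in pregnancy": "2"}),
        _v("Gravida", ["0", "1", "2", m], "history",
           {"Nulligravida": "0", "Primigravida": "1", "Multigravida": "2"}),
        _v("Parity", ["0", "1", "2", m], "history",
           {"Nulliparity": "0", "Low Multiparity (1-2)": "1", "Grand Multiparity (>=3)": "2"}),
        _v("BMI_Category", ["1", "2", "3", "4", m], "history",
           {"Underweight": "1", "Healthy": "2", "Overweight": "3", "Obese": "4"}),
        _v("Change_in_Weight", ["0", "1", "2", m], "history",
           {"Low": "0", "Normal": "1", "High": "2"}),
        _binary("Folic_Acid", "history"),
        _binary("Multivitamin", "history"),
        _binary("PHx_GDM", "history"),
        _binary("PCOS", "history"),
        _binary("History_of_Large_Baby", "history"),
        _binary("Family_History_of_Diabetes", "history"),
        _binary("Previous_Obstetric_History", "history"),
        _binary("History_of_Multiple_Pregnancies", "history"),
        _binary("History_of_Miscarriage", "history"),
        _binary("History_of_PET", "history"),
        _binary("Insulin_used_previously", "history"),
        _binary("Fertility_Treatment", "history"),
        # diagnostics
        _v("Gestation_at_diagnosis", ["1", "2", "3", m], "diagnostic",
           {"First trimester": "1", "Second trimester": "2", "Third trimester": "3"}),
        _v("GTT_Location", ["1", "2", "3", "4", m], "diagnostic",
           {"CUH": "1", "GP": "2", "Private rooms": "3", "Other": "4"}),
        _v("GTT_Result", ["1", "2", m], "diagnostic", {"Normal": "1", "At/High risk": "2"}),
        _v("HbA1c_at_diagnosis", ["1", "2", "3", "4", m], "diagnostic",
           {"<35": "1", "35-40": "2", "41-47": "3", ">48": "4"}),
        _v("Growth", ["0", "1", "2", "3", "4", m], "diagnostic",
           {"Very Low": "0", "Low": "1", "Normal": "2", "High": "3", "Very High": "4"}),
        _v("AC", ["0", "1", "2", m], "diagnostic",
           {"Small": "0", "Appropriate": "1", "Large": "2"}),
        # treatment
        _binary("Diet_Only", "treatment"),
        _binary("Referral_to_Endocrinology", "treatment"),
        _binary("Metformin", "treatment"),
        _binary("Basal_Insulin", "treatment"),
        _binary("Prandial_Insulin", "treatment"),
        _binary("Induction_of_labour", "treatment"),
        # outcomes (maternal / delivery / neonatal / postnatal)
        _binary("Pregnancy_Complications", "outcome"),
        _binary("Polyhydramnios", "outcome"),
        _v("Gestation_at_delivery", ["1", "2", "3", m], "outcome",
           {"First trimester": "1", "Second trimester": "2", "Third trimester": "3"}),
        _binary("Live_infant", "outcome"),
        _binary("NVD", "outcome"),
        _binary("Operative_delivery", "outcome"),
        _binary("Instrumental_delivery", "outcome"),
        _binary("Maternal_trauma", "outcome"),
        _binary("Shoulder_dystocia", "outcome"),
        _v("Birth_weight", ["1", "2", "3", "4", "5", m], "outcome",
           {"Macrosomic": "1", "Normal": "2", "LBW": "3", "VLBW": "4", "ELBW": "5"}),
        _binary("Macrosomia", "outcome"),
        _v("NICUadmission", ["1", "2", m], "outcome", {"Yes": "1", "No": "2"}),
        _binary("Trauma_to_baby", "outcome"),
        _binary("Hypoglycaemia_in_infant", "outcome"),
        _binary("Jaundice_in_infant", "outcome"),
        _binary("Breastfeeding_on_discharge", "outcome"),
        _binary("Postnatal_GTT", "outcome"),
        _v("Fasting", ["1", "2", m], "outcome", {"Normal": "1", "At/High risk": "2"}),
        _v("2HRPPpost", ["1", "2", m], "outcome", {"Normal": "1", "At/High risk": "2"}),
        _v("HbA1c_post", ["1", "2", m], "outcome", {"Normal": "1", "At/High risk": "2"}),
    ]
    assert len(specs) == 62, f"schema has {len(specs)} variables, expected 62"
    assert len({s.name for s in specs}) == 62
    return specs


def schema_to_dict(schema: list[VariableSpec]) -> list[dict]:
    """JSON/YAML-serialisable form of a schema."""
    return [
        {"name": s.name, "states": list(s.states), "role": s.role,
         "quantisation": dict(s.quantisation)}
        for s in schema
    ]


def schema_from_dict(items: list[dict]) -> list[VariableSpec]:
    return [
        VariableSpec(d["name"], tuple(d["states"]), d.get("role", "diagnostic"),
                     dict(d.get("quantisation", {})))
        for d in items
    ]
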