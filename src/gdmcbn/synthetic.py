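"""Synthetic GDM-like cohorts from a known ground-truth causal network.

The real cohort this package's pipeline targets (routinely collected
maternity records) cannot be distributed, so everything downstream is
exercised on data drawn from a fully specified causal Bayesian network:
a 62-node clinical knowledge graph (synthetic stand-in, hand-written to
encode standard antenatal care pathways) with Dirichlet-random CPTs,
forward-sampled and then overlaid with a configurable missingness
mechanism that rewrites cells to the literal state ``"99"``.

Ground-truth CPTs place zero mass on the missing state: the structural
model generates complete records and missingness is applied as a
separate observation process, MCAR (a flat per-variable rate) or MAR
(rate depending on the values of designated conditioning variables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cbn import Cbn, Cpt
from .dataset import DiscreteDataset
from .graphs import CycleError, Dag
from .schema import MISSING, VariableSpec, build_gdm_schema

__all__ = [
    "MissingnessSpec",
    "GroundTruthModel",
    "DEFAULT_GDM_EDGES",
    "build_ground_truth",
    "default_missingness",
    "study_ground_truth",
    "sample_dataset",
    "apply_missingness",
    "sample_study_cohort",
    "make_toy_network",
    "STUDY_N",
]

STUDY_N = 1808  # default cohort size of the study-scale preset


# --------------------------------------------------------------- ground truth

#: Synthetic 62-node knowledge graph: 75 directed edges encoding the
#: clinical care pathway (demographics -> history -> diagnosis ->
#: treatment -> delivery -> neonatal -> postnatal follow-up).
DEFAULT_GDM_EDGES: tuple[tuple[str, str], ...] = (
    ("Age", "BMI_Category"),
    ("Age", "Gravida"),
    ("Ethnicity", "Diabetes"),
    ("Ethnicity", "BMI_Category"),
    ("Occupation", "Smoking"),
    ("Occupation", "Patient_Type"),
    ("Marital_Status", "Depression"),
    ("Patient_Type", "GTT_Location"),
    ("BMI_Category", "Diabetes"),
    ("BMI_Category", "Previous_Bariatric_Surgery"),
    ("BMI_Category", "Change_in_Weight"),
    ("PCOS", "Fertility_Treatment"),
    ("PCOS", "PHx_GDM"),
    ("Family_History_of_Diabetes", "Diabetes"),
    ("Diabetes", "Medical_History"),
    ("Thyroid", "Medical_History"),
    ("Hypertension", "Medical_History"),
    ("PHx_GDM", "Insulin_used_previously"),
    ("PHx_GDM", "Gestation_at_diagnosis"),
    ("History_of_Large_Baby", "PHx_GDM"),
    ("Gravida", "Parity"),
    ("Parity", "History_of_Multiple_Pregnancies"),
    ("Parity", "History_of_Large_Baby"),
    ("History_of_Miscarriage", "Previous_Obstetric_History"),
    ("History_of_PET", "Previous_Obstetric_History"),
    ("History_of_Multiple_Pregnancies", "Previous_Obstetric_History"),
    ("Smoking", "No_of_Cigarettes_per_day"),
    ("Smoking", "Pregnancy_Complications"),
    ("Smoking", "Birth_weight"),
    ("Alcohol", "Pregnancy_Complications"),
    ("Depression", "Smoking"),
    ("Previous_Bariatric_Surgery", "Change_in_Weight"),
    ("Hypertension", "Pregnancy_Complications"),
    ("History_of_PET", "Pregnancy_Complications"),
    ("Folic_Acid", "Multivitamin"),
    ("GTT_Location", "GTT_Result"),
    ("GTT_Result", "HbA1c_at_diagnosis"),
    ("GTT_Result", "Referral_to_Endocrinology"),
    ("Diabetes", "HbA1c_at_diagnosis"),
    ("AC", "Growth"),
    ("HbA1c_at_diagnosis", "AC"),
    ("GTT_Result", "Diet_Only"),
    ("Diet_Only", "Metformin"),
    ("Metformin", "Basal_Insulin"),
    ("Basal_Insulin", "Prandial_Insulin"),
    ("Referral_to_Endocrinology", "Basal_Insulin"),
    ("Growth", "Induction_of_labour"),
    ("Diabetes", "Polyhydramnios"),
    ("Polyhydramnios", "Pregnancy_Complications"),
    ("NVD", "Maternal_trauma"),
    ("Pregnancy_Complications", "Gestation_at_delivery"),
    ("Induction_of_labour", "Gestation_at_delivery"),
    ("Gestation_at_delivery", "Birth_weight"),
    ("Growth", "Birth_weight"),
    ("Birth_weight", "Macrosomia"),
    ("Birth_weight", "NICUadmission"),
    ("Live_infant", "NICUadmission"),
    ("Hypoglycaemia_in_infant", "NICUadmission"),
    ("Trauma_to_baby", "NICUadmission"),
    ("Gestation_at_delivery", "Live_infant"),
    ("Induction_of_labour", "Operative_delivery"),
    ("Operative_delivery", "NVD"),
    ("Instrumental_delivery", "NVD"),
    ("Macrosomia", "Shoulder_dystocia"),
    ("Shoulder_dystocia", "Trauma_to_baby"),
    ("History_of_Multiple_Pregnancies", "Trauma_to_baby"),
    ("Birth_weight", "Maternal_trauma"),
    ("Operative_delivery", "Maternal_trauma"),
    ("Birth_weight", "Hypoglycaemia_in_infant"),
    ("Gestation_at_delivery", "Jaundice_in_infant"),
    ("NICUadmission", "Breastfeeding_on_discharge"),
    ("Referral_to_Endocrinology", "Postnatal_GTT"),
    ("Postnatal_GTT", "2HRPPpost"),
    ("Diet_Only", "Fasting"),
    ("HbA1c_at_diagnosis", "HbA1c_post"),
)


@dataclass(frozen=True)
class MissingnessSpec:
    """Observation process for one variable.

    ``mechanism`` is MCAR (flat ``rate``) or MAR (rate looked up in
    ``rate_map`` by the tuple of the conditioning ``parents``' observed
    state labels, falling back to ``rate``).
    """

    mechanism: str = "MCAR"
    rate: float = 0.0
    parents: tuple[str, ...] = ()
    rate_map: dict[tuple[str, ...], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        rates = [self.rate, *self.rate_map.values()]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("missingness rates must lie in [0, 1]")
        if self.mechanism == "MAR" and not self.parents:
            raise ValueError("MAR requires at least one conditioning parent")
        if self.mechanism == "MCAR" and self.parents:
            raise ValueError("MCAR takes no conditioning parents")


@dataclass
class GroundTruthModel:
    """A known generator: schema + DAG + CPTs + missingness mechanisms."""

    schema: list[VariableSpec]
    dag: Dag
    cpts: dict[str, Cpt]
    missingness: dict[str, MissingnessSpec]
    seed: int

    def __post_init__(self):
        names = {s.name for s in self.schema}
        if self.dag.nodes != names:
            raise ValueError("DAG nodes must equal schema variable names")
        for var, spec in self.missingness.items():
            if var not in names:
                raise ValueError(f"missingness on unknown variable {var!r}")
            if spec.rate > 0 or any(r > 0 for r in spec.rate_map.values()):
                if MISSING not in self._spec(var).states:
                    raise ValueError(
                        f"{var!r} has missingness rate > 0 but no {MISSING!r} state"
                    )
            for p in spec.parents:
                if p not in names:
                    raise ValueError(f"MAR conditioning variable {p!r} unknown")

    def _spec(self, name: str) -> VariableSpec:
        return next(s for s in self.schema if s.name == name)

    def to_cbn(self) -> Cbn:
        states = {s.name: tuple(s.states) for s in self.schema}
        return Cbn(self.dag, self.cpts, states)


def build_ground_truth(
    schema: list[VariableSpec],
    reference_edges: list[tuple[str, str]],
    seed: int = 0,
    dirichlet_alpha: float = 0.5,
    missingness: dict[str, MissingnessSpec] | None = None,
) -> GroundTruthModel:
    """Deterministic ground truth: given edges, CPT rows ~ Dirichlet(alpha).

    CPT rows are drawn over the non-missing states only (the missing
    column gets probability zero); nodes absent from the edge list
    become parentless.  Identical inputs yield identical models.
    """
    if dirichlet_alpha <= 0:
        raise ValueError("dirichlet_alpha must be positive")
    names = [s.name for s in schema]
    name_set = set(names)
    for u, v in reference_edges:
        if u not in name_set or v not in name_set:
            raise ValueError(f"edge ({u},{v}) mentions a variable outside the schema")
    dag = Dag(name_set, reference_edges)  # raises CycleError with the cycle

    by_name = {s.name: s for s in schema}
    rng = np.random.default_rng(seed)
    cpts: dict[str, Cpt] = {}
    for node in names:  # schema order fixes the RNG stream
        spec = by_name[node]
        parents = tuple(sorted(dag.parents(node)))
        q = 1
        for p in parents:
            q *= by_name[p].cardinality
        live = [i for i, s in enumerate(spec.states) if s != MISSING]
        table = np.zeros((q, spec.cardinality))
        draws = rng.dirichlet(np.full(len(live), dirichlet_alpha), size=q)
        table[:, live] = draws
        cpts[node] = Cpt(node, parents, table)
    return GroundTruthModel(list(schema), dag, cpts, dict(missingness or {}), seed)


def default_missingness(schema: list[VariableSpec]) -> dict[str, MissingnessSpec]:
    """Study-scale missingness preset, assigned by variable class.

    Postnatal labs and fragile neonatal fields are heavily missing
    (above 0.70 for neonatal hypoglycaemia, neonatal trauma and the
    2-hour postprandial test), history fields moderately (0.10-0.30),
    demographics lightly.  Maternal depression and prior bariatric
    surgery carry a MAR mechanism conditioned on patient type, standing
    in for documentation patterns that differ between care settings.
    """
    high = {"Hypoglycaemia_in_infant": 0.78, "Trauma_to_baby": 0.74, "2HRPPpost": 0.72,
            "HbA1c_post": 0.60, "Fasting": 0.55, "Postnatal_GTT": 0.50,
            "Jaundice_in_infant": 0.45, "Breastfeeding_on_discharge": 0.35}
    out: dict[str, MissingnessSpec] = {}
    for s in schema:
        if s.name in high:
            out[s.name] = MissingnessSpec("MCAR", high[s.name])
        elif s.name in ("Depression", "Previous_Bariatric_Surgery"):
            out[s.name] = MissingnessSpec(
                "MAR", 0.45, ("Patient_Type",),
                {("0",): 0.45, ("1",): 0.20, (MISSING,): 0.45},
            )
        elif s.role == "history":
            out[s.name] = MissingnessSpec("MCAR", 0.15)
        elif s.role == "outcome":
            out[s.name] = MissingnessSpec("MCAR", 0.18)
        elif s.role == "diagnostic":
            out[s.name] = MissingnessSpec("MCAR", 0.12)
        elif s.role == "treatment":
            out[s.name] = MissingnessSpec("MCAR", 0.10)
        else:  # demographic
            out[s.name] = MissingnessSpec("MCAR", 0.04)
    return out


def study_ground_truth(seed: int = 0, dirichlet_alpha: float = 0.5) -> GroundTruthModel:
    """The study-scale preset: 62 variables, 75 edges, default missingness."""
    schema = build_gdm_schema()
    return build_ground_truth(
        schema, list(DEFAULT_GDM_EDGES), seed=seed, dirichlet_alpha=dirichlet_alpha,
        missingness=default_missingness(schema),
    )


# --------------------------------------------------------------- sampling

def sample_dataset(model: GroundTruthModel, n: int, seed: int = 0) -> DiscreteDataset:
    """Forward-sample n complete rows in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = [s.name for s in model.schema]
    col = {name: j for j, name in enumerate(names)}
    cards = {s.name: s.cardinality for s in model.schema}
    codes = np.zeros((n, len(names)), dtype=np.int32)
    for node in model.dag.topological_order():
        cpt = model.cpts[node]
        cfg = np.zeros(n, dtype=np.int64)
        for p in cpt.parents:
            cfg = cfg * cards[p] + codes[:, col[p]]
        probs = cpt.table[cfg]  # (n, r)
        u = rng.random(n)
        codes[:, col[node]] = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
    return DiscreteDataset(model.schema, codes)


def apply_missingness(
    data: DiscreteDataset, model: GroundTruthModel, seed: int = 0
) -> DiscreteDataset:
    """Overlay the model's missingness mechanisms, cell -> ``"99"``.

    Each variable is masked independently, with rates computed from the
    *input* data's values (so the result does not depend on the order
    in which variables are processed).  Non-missing cells are never
    altered and no rows are dropped.
    """
    rng = np.random.default_rng(seed)
    codes = data.codes.copy()
    for name in [s.name for s in data.schema]:  # fixed order for the RNG stream
        spec_m = model.missingness.get(name)
        if spec_m is None:
            continue
        var = data.spec(name)
        if spec_m.mechanism == "MCAR":
            rates = np.full(data.n, spec_m.rate)
        else:  # MAR: per-row rate from conditioning variables' observed values
            rates = np.full(data.n, spec_m.rate)
            parent_cols = [data.column(p) for p in spec_m.parents]
            parent_specs = [data.spec(p) for p in spec_m.parents]
            for combo, r in spec_m.rate_map.items():
                mask = np.ones(data.n, dtype=bool)
                for pcol, pspec, lab in zip(parent_cols, parent_specs, combo):
                    mask &= pcol == pspec.index_of(lab)
                rates[mask] = r
        if not (rates > 0).any():
            continue
        if not var.can_be_missing:
            raise ValueError(f"{name!r} has no {MISSING!r} state but a positive rate")
        hit = rng.random(data.n) < rates
        codes[hit, data.column_index(name)] = var.index_of(MISSING)
    return DiscreteDataset(data.schema, codes)


def sample_study_cohort(seed: int = 0, n: int = STUDY_N) -> tuple[GroundTruthModel, DiscreteDataset]:
    """Convenience: study-scale ground truth + masked cohort of n rows."""
    model = study_ground_truth(seed=seed)
    complete = sample_dataset(model, n, seed=seed + 1)
    return model, apply_missingness(complete, model, seed=seed + 2)


# --------------------------------------------------------------- toy fixtures

def _cbn(edges: list[tuple[str, str]], cpts: dict[str, tuple[tuple[str, ...], list[list[float]]]]) -> Cbn:
    nodes = set(cpts)
    dag = Dag(nodes, edges)
    states = {v: ("0", "1") for v in nodes}
    built = {v: Cpt(v, parents, np.array(tab)) for v, (parents, tab) in cpts.items()}
    return Cbn(dag, built, states)


def make_toy_network(name: str) -> Cbn:
    """Small fully specified binary CBNs for exact-inference oracles.

    ``chain``      X -> Y -> Z
    ``collider``   X -> Z <- Y   (X and Y marginally independent)
    ``confounder`` Z -> X, Z -> Y, X -> Y
    ``sprinkler``  Cloudy -> {Sprinkler, Rain} -> Wet
    """
    if name == "chain":
        return _cbn(
            [("X", "Y"), ("Y", "Z")],
            {
                "X": ((), [[0.7, 0.3]]),
                "Y": (("X",), [[0.8, 0.2], [0.25, 0.75]]),
                "Z": (("Y",), [[0.9, 0.1], [0.15, 0.85]]),
            },
        )
    if name == "collider":
        return _cbn(
            [("X", "Z"), ("Y", "Z")],
            {
                "X": ((), [[0.6, 0.4]]),
                "Y": ((), [[0.65, 0.35]]),
                "Z": (("X", "Y"), [[0.95, 0.05], [0.5, 0.5], [0.4, 0.6], [0.1, 0.9]]),
            },
        )
    if name == "confounder":
        return _cbn(
            [("Z", "X"), ("Z", "Y"), ("X", "Y")],
            {
                "Z": ((), [[0.55, 0.45]]),
                "X": (("Z",), [[0.75, 0.25], [0.3, 0.7]]),
                # rows: (X=0,Z=0), (X=0,Z=1), (X=1,Z=0), (X=1,Z=1)
                "Y": (("X", "Z"), [[0.9, 0.1], [0.6, 0.4], [0.5, 0.5], [0.2, 0.8]]),
            },
        )
    if name == "sprinkler":
        return _cbn(
            [("Cloudy", "Sprinkler"), ("Cloudy", "Rain"),
             ("Sprinkler", "Wet"), ("Rain", "Wet")],
            {
                "Cloudy": ((), [[0.5, 0.5]]),
                "Sprinkler": (("Cloudy",), [[0.5, 0.5], [0.9, 0.1]]),
                "Rain": (("Cloudy",), [[0.8, 0.2], [0.2, 0.8]]),
                # rows: (Rain=0,Sprinkler=0), (0,1), (1,0), (1,1)
                "Wet": (("Rain", "Sprinkler"), [[1.0, 0.0], [0.1, 0.9], [0.2, 0.8], [0.01, 0.99]]),
            },
        )
    raise ValueError(f"unknown toy network {name!r}; "
                     "choose from chain, collider, confounder, sprinkler")
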