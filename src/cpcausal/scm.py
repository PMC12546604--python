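"""Structural causal model behind the synthetic Cell-Painting experiments.

The simulator encodes the causal graph of a confounded high-content screen:
confounders C (source lab, batch/plate, well position) influence which
compound T lands in which well (C -> T), the true cellular phenotype
(C -> P), and the imaging process itself (C -> O); the treatment influences
the phenotype (T -> P); and the phenotype is observed only through noisy
multi-channel images (P -> O).

All mechanisms are linear-Gaussian so that the interventional mean
E[P | do(T = t)] has a closed form (:func:`interventional_mean`) against
which every Monte-Carlo adjustment estimate can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .utils import as_rng, check_finite

CONTROL_COMPOUND = "DMSO"

#: channel order used everywhere; DNA must sit at index 0 for the
#: channel-duplication rule of the latent encoder.
CHANNELS = ("DNA", "ER", "RNA", "AGP", "Mito")

#: number of renderer parameters driven by confounders:
#: (gradient_x, gradient_y, background_offset, blur)
RENDER_PARAM_DIM = 4

#: number of well-position quadrants used in the confounder code
N_QUADRANTS = 4


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfounderAssignment:
    """One realized confounder combination C for a single field of view."""

    source_id: str
    batch_id: str
    plate_id: str
    well_row: int
    well_col: int
    fov_index: int = 0

    @property
    def well_name(self) -> str:
        return f"{chr(ord('A') + self.well_row)}{self.well_col + 1:02d}"


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    moa_label: str | None
    target_labels: frozenset[str]
    is_control: bool = False

    def __post_init__(self):
        if self.is_control != (self.smiles == CONTROL_COMPOUND):
            raise ValueError(
                "is_control must hold exactly when smiles is the control token "
                f"{CONTROL_COMPOUND!r}"
            )


@dataclass
class ObservationRecord:
    """One acquired image O with its treatment T and confounders C.

    ``phenotype`` is the hidden ground-truth P; it exists for evaluation only
    and must never be read by inference code paths.
    """

    image: np.ndarray
    compound_id: str
    confounders: ConfounderAssignment
    phenotype: np.ndarray


@dataclass
class ExperimentDesign:
    """Plate layout and treatment allocation of one synthetic screen."""

    sources: list[str]
    batches: list[tuple[str, str]]  # (source, batch_id)
    plates: dict[str, tuple[str, int, int]]  # plate -> (batch, n_rows, n_cols)
    wells: dict[str, list[tuple[int, int]]]
    fovs_per_well: int
    allocation: dict[tuple[str, tuple[int, int]], str]

    def __post_init__(self):
        batch_ids = {b for _, b in self.batches}
        for plate, (batch, n_rows, n_cols) in self.plates.items():
            if batch not in batch_ids:
                raise ValueError(f"plate {plate} references unknown batch {batch}")
            for r, c in self.wells[plate]:
                if not (0 <= r < n_rows and 0 <= c < n_cols):
                    raise ValueError(f"well ({r},{c}) outside plate {plate} bounds")
        for plate in self.plates:
            labels = [self.allocation[(plate, w)] for w in self.wells[plate]]
            if CONTROL_COMPOUND not in labels:
                raise ValueError(f"plate {plate} has no control well")

    @property
    def batch_source(self) -> dict[str, str]:
        return {b: s for s, b in self.batches}

    @property
    def plate_shape(self) -> dict[str, tuple[int, int]]:
        return {p: (r, c) for p, (_, r, c) in self.plates.items()}

    def iter_assignments(self):
        """Yield (assignment, compound_id) for every (plate, well, fov)."""
        src = self.batch_source
        for plate, (batch, _, _) in self.plates.items():
            for r, c in self.wells[plate]:
                for fov in range(self.fovs_per_well):
                    yield (
                        ConfounderAssignment(src[batch], batch, plate, r, c, fov),
                        self.allocation[(plate, (r, c))],
                    )

    def n_observations(self) -> int:
        return sum(len(w) for w in self.wells.values()) * self.fovs_per_well


@dataclass
class ScmParams:
    """Functional mechanisms of the causal graph.

    ``compound_effect`` is the T->P map (phenotype_dim x embedding_dim),
    ``confounder_effect_phenotype`` the C->P map (phenotype_dim x code_dim),
    ``confounder_effect_observation`` the C->O map (4 x code_dim) feeding the
    renderer's gradient/offset/blur parameters, ``allocation_bias`` the
    strength of the C->T edge, and ``phenotype_noise_sd`` the biological
    noise scale.
    """

    compound_effect: np.ndarray
    confounder_effect_phenotype: np.ndarray
    confounder_effect_observation: np.ndarray
    allocation_bias: float = 0.0
    phenotype_noise_sd: float = 0.3

    def __post_init__(self):
        self.compound_effect = check_finite(
            np.atleast_2d(np.asarray(self.compound_effect, dtype=float)),
            "compound_effect",
        )
        self.confounder_effect_phenotype = check_finite(
            np.atleast_2d(np.asarray(self.confounder_effect_phenotype, dtype=float)),
            "confounder_effect_phenotype",
        )
        self.confounder_effect_observation = check_finite(
            np.atleast_2d(np.asarray(self.confounder_effect_observation, dtype=float)),
            "confounder_effect_observation",
        )
        if self.phenotype_noise_sd <= 0:
            raise ValueError("phenotype_noise_sd must be > 0")
        if self.allocation_bias < 0:
            raise ValueError("allocation_bias must be >= 0")
        p = self.compound_effect.shape[0]
        if self.confounder_effect_phenotype.shape[0] != p:
            raise ValueError("confounder_effect_phenotype rows must equal phenotype_dim")
        if self.confounder_effect_observation.shape[0] != RENDER_PARAM_DIM:
            raise ValueError(
                f"confounder_effect_observation must have {RENDER_PARAM_DIM} rows"
            )

    @property
    def phenotype_dim(self) -> int:
        return self.compound_effect.shape[0]

    @property
    def embedding_dim(self) -> int:
        return self.compound_effect.shape[1]

    @property
    def confounder_code_dim(self) -> int:
        return self.confounder_effect_phenotype.shape[1]

    @classmethod
    def random(
        cls,
        phenotype_dim: int,
        embedding_dim: int,
        confounder_code_dim: int,
        seed: int | np.random.Generator = 0,
        compound_scale: float = 2.0,
        confounder_phenotype_scale: float = 0.6,
        confounder_observation_scale: float = 0.5,
        allocation_bias: float = 0.0,
        phenotype_noise_sd: float = 0.3,
    ) -> "ScmParams":
        """Draw a random parameterization with the given effect scales.

        Effect matrices are Gaussian with per-row normalization so that a
        unit-norm embedding / one-hot-block confounder code produces
        phenotype shifts of roughly ``compound_scale`` /
        ``confounder_phenotype_scale`` per coordinate.
        """
        rng = as_rng(seed)
        A = rng.standard_normal((phenotype_dim, embedding_dim))
        A *= compound_scale / np.sqrt(embedding_dim / 3.0)
        B = rng.standard_normal((phenotype_dim, confounder_code_dim))
        B *= confounder_phenotype_scale / np.sqrt(3.0)
        W = rng.standard_normal((RENDER_PARAM_DIM, confounder_code_dim))
        W *= confounder_observation_scale / np.sqrt(3.0)
        return cls(A, B, W, allocation_bias, phenotype_noise_sd)


# ---------------------------------------------------------------------------
# confounder codes
# ---------------------------------------------------------------------------


def well_quadrant(row: int, col: int, n_rows: int, n_cols: int) -> int:
    """Quadrant index 0-3 of a well position (top-left, top-right, bottom-left, bottom-right)."""
    return 2 * int(row >= n_rows / 2) + int(col >= n_cols / 2)


def confounder_code(assignment: ConfounderAssignment, design: ExperimentDesign) -> np.ndarray:
    """One-hot concatenation of (source, batch, well-quadrant).

    This is the numeric representation of C fed to the linear mechanisms;
    FoV deliberately has no causal effect (it is an auxiliary imaging
    condition, not a confounder).
    """
    sources = design.sources
    batch_ids = [b for _, b in design.batches]
    code = np.zeros(len(sources) + len(batch_ids) + N_QUADRANTS)
    try:
        code[sources.index(assignment.source_id)] = 1.0
        code[len(sources) + batch_ids.index(assignment.batch_id)] = 1.0
    except ValueError as e:
        raise ValueError(f"assignment outside design: {assignment}") from e
    n_rows, n_cols = design.plate_shape[assignment.plate_id]
    q = well_quadrant(assignment.well_row, assignment.well_col, n_rows, n_cols)
    code[len(sources) + len(batch_ids) + q] = 1.0
    return code


def confounder_code_dim(design: ExperimentDesign) -> int:
    return len(design.sources) + len(design.batches) + N_QUADRANTS


def enumerate_confounder_codes(design: ExperimentDesign) -> np.ndarray:
    """All distinct (source, batch, quadrant) codes realizable in a design."""
    codes = []
    seen = set()
    for assignment, _ in design.iter_assignments():
        key = (
            assignment.batch_id,
            well_quadrant(
                assignment.well_row,
                assignment.well_col,
                *design.plate_shape[assignment.plate_id],
            ),
        )
        if key not in seen:
            seen.add(key)
            codes.append(confounder_code(assignment, design))
    return np.array(codes)


# ---------------------------------------------------------------------------
# design construction (the C -> T edge)
# ---------------------------------------------------------------------------


def make_design(
    n_sources: int = 3,
    n_batches_per_source: int = 2,
    n_plates_per_batch: int = 2,
    plate_rows: int = 8,
    plate_cols: int = 12,
    fovs_per_well: int = 2,
    compounds: list[CompoundRecord] | None = None,
    allocation_bias: float = 0.0,
    seed: int | np.random.Generator = 0,
    replicate: bool = True,
    controls_per_plate: int | None = None,
) -> ExperimentDesign:
    """Build a plate layout and allocate compounds to wells.

    The C -> T edge is realized by softmax-weighted compound sampling per
    batch: each (batch, compound) pair gets an i.i.d. standard-normal
    affinity ``w`` and treatment wells in that batch draw compounds with
    probability softmax(allocation_bias * w). ``allocation_bias = 0`` gives
    uniform allocation; larger values concentrate each compound in a few
    batches, mimicking incompletely randomized plate maps.
    """
    if min(n_sources, n_batches_per_source, n_plates_per_batch, plate_rows,
           plate_cols, fovs_per_well) < 1:
        raise ValueError("all design counts must be >= 1")
    if not compounds:
        raise ValueError("compounds must be non-empty")
    rng = as_rng(seed)

    treatments = [c.compound_id for c in compounds if not c.is_control]
    if not any(c.is_control for c in compounds):
        raise ValueError(f"compound list must include the {CONTROL_COMPOUND} control")
    if not treatments:
        raise ValueError("compound list has no treatment compounds")

    sources = [f"S{i + 1}" for i in range(n_sources)]
    batches = [
        (s, f"{s}_B{j + 1}") for s in sources for j in range(n_batches_per_source)
    ]
    plates: dict[str, tuple[str, int, int]] = {}
    wells: dict[str, list[tuple[int, int]]] = {}
    for _, b in batches:
        for k in range(n_plates_per_batch):
            plate = f"{b}_P{k + 1}"
            plates[plate] = (b, plate_rows, plate_cols)
            wells[plate] = [
                (r, c) for r in range(plate_rows) for c in range(plate_cols)
            ]

    n_wells = plate_rows * plate_cols
    if controls_per_plate is None:
        controls_per_plate = max(1, n_wells // 12)
    if controls_per_plate >= n_wells:
        raise ValueError("controls_per_plate must leave at least one treatment well")
    n_treatment_wells = (n_wells - controls_per_plate) * len(plates)
    if not replicate and len(treatments) > n_treatment_wells:
        raise ValueError(
            f"{len(treatments)} compounds exceed {n_treatment_wells} treatment wells "
            "with replication disabled"
        )

    # evenly spread control wells over the serpentine well order
    ctrl_idx = np.linspace(0, n_wells - 1, controls_per_plate).round().astype(int)

    # per-(batch, compound) affinities define the biased allocation
    affinity = rng.standard_normal((len(batches), len(treatments)))
    allocation: dict[tuple[str, tuple[int, int]], str] = {}
    batch_index = {b: i for i, (_, b) in enumerate(batches)}
    plates_of_batch: dict[str, list[str]] = {}
    for plate, (batch, _, _) in plates.items():
        plates_of_batch.setdefault(batch, []).append(plate)

    free: dict[str, list[tuple[int, int]]] = {}
    for plate in plates:
        well_list = wells[plate]
        ctrl_wells = {well_list[i] for i in ctrl_idx}
        for w in ctrl_wells:
            allocation[(plate, w)] = CONTROL_COMPOUND
        free[plate] = [w for w in well_list if w not in ctrl_wells]

    # every compound is screened at least once; its guaranteed well lands in
    # a batch drawn with the same biased preference, preserving the C-T edge
    if replicate and len(treatments) <= n_treatment_wells:
        for k in rng.permutation(len(treatments)):
            logits = allocation_bias * affinity[:, k]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            for _ in range(100):
                batch = batches[rng.choice(len(batches), p=p)][1]
                candidates = [pl for pl in plates_of_batch[batch] if free[pl]]
                if candidates:
                    plate = candidates[rng.integers(len(candidates))]
                    w = free[plate].pop(rng.integers(len(free[plate])))
                    allocation[(plate, w)] = treatments[k]
                    break
            else:  # all preferred batches full: any free well
                plate = next(pl for pl in plates if free[pl])
                w = free[plate].pop(rng.integers(len(free[plate])))
                allocation[(plate, w)] = treatments[k]

    unused = list(range(len(treatments)))  # for replicate=False coverage
    for plate, (batch, _, _) in plates.items():
        logits = allocation_bias * affinity[batch_index[batch]]
        p = np.exp(logits - logits.max())
        p /= p.sum()
        for w in free[plate]:
            if replicate:
                allocation[(plate, w)] = treatments[rng.choice(len(treatments), p=p)]
            elif unused:
                allocation[(plate, w)] = treatments[unused.pop(0)]
            else:  # replication disabled: spare wells become controls
                allocation[(plate, w)] = CONTROL_COMPOUND

    return ExperimentDesign(sources, batches, plates, wells, fovs_per_well, allocation)


# ---------------------------------------------------------------------------
# compound library (fragment-grammar SMILES-like strings)
# ---------------------------------------------------------------------------

_FRAGMENT_POOL = (
    "C1CCCCC1", "c1ccccc1", "c1ccncc1", "C1CCNCC1", "N1CCOCC1", "C1CCOC1",
    "N(C)C", "C(=O)O", "C(=O)N", "C#N", "C(F)(F)F", "S(=O)(=O)N",
    "OCC", "OC(C)C", "CNC(=O)", "C=CC", "NC(=N)N", "c1ccsc1",
    "C1CC1", "n1ccnc1", "CCl", "CBr", "C(C)(C)C", "OCO",
)


def make_compound_library(
    n_compounds: int = 40,
    n_moa_classes: int = 4,
    n_target_labels: int = 8,
    fragments_per_class: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[CompoundRecord]:
    """Build a compound library with class-indicative structure.

    SMILES-like strings are assembled from a fragment grammar: compounds
    sharing an MoA share ``fragments_per_class`` class fragments, so their
    hashed n-gram embeddings are more similar within class than between —
    the structural signal unseen-compound generalization relies on. Each
    compound receives one MoA and 1-3 targets drawn from a class-linked
    target pool. The DMSO control is appended as the last record.
    """
    if n_compounds < n_moa_classes:
        raise ValueError("need at least one compound per MoA class")
    rng = as_rng(seed)

    moas = [f"MoA_{i + 1:02d}" for i in range(n_moa_classes)]
    targets = [f"TGT_{i + 1:02d}" for i in range(n_target_labels)]
    # each MoA owns a small set of plausible targets (overlap allowed)
    per_class_targets = [
        [targets[(2 * k + j) % n_target_labels] for j in range(3)]
        for k in range(n_moa_classes)
    ]
    # distinct class fragments, cycling through the pool
    frag_of_class = [
        [
            _FRAGMENT_POOL[(k * fragments_per_class + j) % len(_FRAGMENT_POOL)]
            for j in range(fragments_per_class)
        ]
        for k in range(n_moa_classes)
    ]

    records = []
    for i in range(n_compounds):
        k = i % n_moa_classes  # balanced classes
        n_filler = int(rng.integers(1, 4))
        filler = [ _FRAGMENT_POOL[j] for j in rng.choice(len(_FRAGMENT_POOL), n_filler) ]
        parts = list(frag_of_class[k]) + filler
        order = rng.permutation(len(parts))
        smiles = "".join(parts[j] for j in order)
        n_tgt = int(rng.integers(1, 4))
        tgt = frozenset(
            per_class_targets[k][j]
            for j in rng.choice(len(per_class_targets[k]), n_tgt, replace=False)
        )
        records.append(
            CompoundRecord(f"CPD_{i + 1:04d}", smiles, moas[k], tgt)
        )
    records.append(
        CompoundRecord(CONTROL_COMPOUND, CONTROL_COMPOUND, None, frozenset(), True)
    )
    return records


# ---------------------------------------------------------------------------
# mechanisms
# ---------------------------------------------------------------------------


def sample_phenotype(
    compound_embedding: np.ndarray,
    confounder_code: np.ndarray,
    params: ScmParams,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Draw P = A e + B c + eps with eps ~ N(0, phenotype_noise_sd^2 I)."""
    e = np.asarray(compound_embedding, dtype=float)
    c = np.asarray(confounder_code, dtype=float)
    if e.shape != (params.embedding_dim,):
        raise ValueError(
            f"embedding dim {e.shape} does not match params ({params.embedding_dim},)"
        )
    if c.shape != (params.confounder_code_dim,):
        raise ValueError(
            f"confounder code dim {c.shape} does not match params "
            f"({params.confounder_code_dim},)"
        )
    rng = as_rng(rng)
    mean = params.compound_effect @ e + params.confounder_effect_phenotype @ c
    return mean + params.phenotype_noise_sd * rng.standard_normal(params.phenotype_dim)


def render_params_for(
    confounder_code: np.ndarray, params: ScmParams
) -> np.ndarray:
    """The C -> O mechanism: (gradient_x, gradient_y, offset, blur) drivers."""
    return params.confounder_effect_observation @ np.asarray(confounder_code, float)


def interventional_mean(
    params: ScmParams,
    compound_embedding: np.ndarray,
    confounder_code_distribution: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form E[P | do(T = t)] under the linear-Gaussian mechanisms.

    Averaging the conditional over the confounder marginal (the backdoor
    formula) reduces to ``A e + B E[c]`` here. ``confounder_code_distribution``
    is either the mean code vector or an array of codes (rows) with optional
    ``weights``. This is the oracle every Monte-Carlo adjustment estimate
    is compared against.
    """
    e = np.asarray(compound_embedding, dtype=float)
    if e.shape != (params.embedding_dim,):
        raise ValueError("embedding dimension mismatch")
    dist = np.asarray(confounder_code_distribution, dtype=float)
    if dist.ndim == 1:
        mean_code = dist
    else:
        mean_code = np.average(dist, axis=0, weights=weights)
    if mean_code.shape != (params.confounder_code_dim,):
        raise ValueError("confounder code dimension mismatch")
    return params.compound_effect @ e + params.confounder_effect_phenotype @ mean_code
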