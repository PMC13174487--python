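"""Synthetic single-cell and spatial data with recoverable ground truth.

The generator emulates three layers of structure seen in tumor immune
microenvironments:

* a CD8 T cell differentiation continuum from stem-like (TCF7/IL7R/CCR7/CXCR5
  high) through effector and effector-memory states to terminal exhaustion
  (TOX/HAVCR2/PDCD1/CXCL13 high), parameterized by a latent coordinate
  ``u`` in [0, 1];
* clonal structure, where paired-chain TCR clonotypes have heavy-tailed size
  distributions and a configurable fraction of expanded clones retain
  multiple stem-like members;
* tissue maps in which tumor cells occupy blob-shaped regions and stromal
  immune aggregates of three composition classes (Quiescent, Stimulated,
  Lymphoid) are planted as 2-D Gaussian clusters among scattered background
  immune cells.

Counts are negative binomial with optional dropout (zero inflation). All
randomness flows from a single ``numpy.random.Generator`` seeded by the
config; identical configs produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SimConfig",
    "AggregateSpec",
    "GroundTruth",
    "STATES",
    "REQUIRED_GENES",
    "DEFAULT_GENE_PANEL",
    "archetype_means",
    "default_signatures",
    "well_separated_config",
    "well_separated_tissue_config",
    "simulate_cd8_counts",
    "simulate_clonotypes",
    "simulate_tissue",
]

#: Ordered CD8 states along the differentiation axis. Memory precedes full
#: effector differentiation so that stem-associated genes decline, and
#: exhaustion-associated genes rise, monotonically along u.
STATES = ("stem-like", "effector-memory", "effector", "exhausted")

#: Genes every panel must contain (markers used throughout the pipeline).
REQUIRED_GENES = (
    "CXCL13", "CXCR5", "TCF7", "IL7R", "CCR7",
    "TOX", "HAVCR2", "PDCD1", "GZMB", "CD8A", "MS4A1",
)

_EXTRA_MARKERS = ("GZMK", "PRF1", "NKG7", "SELL", "LAG3", "ENTPD1", "MKI67",
                  "CXCR3", "KLRG1", "GNLY", "KLRD1", "FGFBP2", "CD44", "EOMES")

_N_FILLER = 40

DEFAULT_GENE_PANEL = tuple(
    list(REQUIRED_GENES) + list(_EXTRA_MARKERS)
    + [f"FILLER{i:03d}" for i in range(1, _N_FILLER + 1)]
)

# Per-state archetype mean counts. Baseline (filler) genes sit at 0.5;
# state markers are elevated 8x (=4.0) in their home state. Values chosen
# once so that the four states are separable by signature scoring at
# default sample sizes.
_BASELINE = 0.5
_ARCHETYPES: dict[str, dict[str, float]] = {
    #            stem   emem   eff    exh
    "TCF7":   dict(zip(STATES, (4.0, 1.00, 0.50, 0.25))),
    "IL7R":   dict(zip(STATES, (4.0, 1.50, 0.50, 0.25))),
    "CCR7":   dict(zip(STATES, (4.0, 1.50, 0.50, 0.25))),
    "CXCR5":  dict(zip(STATES, (4.0, 0.75, 0.50, 0.25))),
    "SELL":   dict(zip(STATES, (3.0, 1.00, 0.30, 0.25))),
    "GZMB":   dict(zip(STATES, (0.5, 1.00, 4.00, 1.00))),
    "PRF1":   dict(zip(STATES, (0.5, 1.00, 4.00, 0.75))),
    "NKG7":   dict(zip(STATES, (0.5, 1.00, 4.00, 0.75))),
    "GZMK":   dict(zip(STATES, (0.25, 4.00, 1.50, 0.50))),
    "GNLY":   dict(zip(STATES, (0.50, 1.00, 4.00, 0.75))),
    "KLRD1":  dict(zip(STATES, (0.50, 1.00, 4.00, 0.75))),
    "FGFBP2": dict(zip(STATES, (0.25, 0.75, 3.00, 0.50))),
    "CD44":   dict(zip(STATES, (1.00, 3.00, 1.50, 1.00))),
    "EOMES":  dict(zip(STATES, (0.50, 3.00, 1.00, 1.50))),
    "CXCR3":  dict(zip(STATES, (0.50, 4.00, 1.00, 0.50))),
    "KLRG1":  dict(zip(STATES, (0.25, 3.00, 1.50, 0.50))),
    "TOX":    dict(zip(STATES, (0.25, 0.50, 1.00, 4.00))),
    "HAVCR2": dict(zip(STATES, (0.25, 0.50, 0.75, 4.00))),
    "PDCD1":  dict(zip(STATES, (0.25, 0.50, 0.75, 4.00))),
    "LAG3":   dict(zip(STATES, (0.25, 0.50, 0.75, 3.00))),
    "ENTPD1": dict(zip(STATES, (0.25, 0.50, 0.75, 3.00))),
    "CXCL13": dict(zip(STATES, (0.25, 0.50, 1.00, 4.00))),
    "MKI67":  dict(zip(STATES, (0.30, 0.30, 1.00, 0.50))),
    "CD8A":   dict(zip(STATES, (2.0, 2.00, 2.00, 2.00))),
    "MS4A1":  dict(zip(STATES, (0.05, 0.05, 0.05, 0.05))),
}

# Non-CD8 cell-type expression profiles for tissue simulation (genes not
# listed sit at the filler baseline scaled by `base`).
_TYPE_PROFILES: dict[str, dict] = {
    "B":       {"base": 0.5, "MS4A1": 4.0, "CXCR5": 3.0, "CD8A": 0.05, "CD79A": 4.0},
    "CD4 T":   {"base": 0.5, "IL7R": 2.0, "CCR7": 1.5, "CD8A": 0.05},
    "myeloid": {"base": 0.5, "CD8A": 0.05},
    "tumor":   {"base": 0.5, "CD8A": 0.02, "MS4A1": 0.02},
    "other":   {"base": 0.5},
}

#: Centers of the four state intervals on the latent axis u.
_STATE_CENTERS = dict(zip(STATES, (0.125, 0.375, 0.625, 0.875)))
_STATE_KNOTS = np.array([0.125, 0.375, 0.625, 0.875])


def archetype_means(gene_panel: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene mean count for each CD8 state (rows: states, cols: genes)."""
    panel = list(gene_panel or DEFAULT_GENE_PANEL)
    out = pd.DataFrame(_BASELINE, index=list(STATES), columns=panel, dtype=float)
    for g, per_state in _ARCHETYPES.items():
        if g in out.columns:
            for s, m in per_state.items():
                out.loc[s, g] = m
    return out


def default_signatures() -> dict[str, list[str]]:
    """Marker gene sets for the four CD8 states (used by state scoring)."""
    return {
        "stem-like": ["TCF7", "IL7R", "CCR7", "CXCR5", "SELL"],
        "effector": ["GZMB", "PRF1", "NKG7", "GNLY", "KLRD1", "FGFBP2"],
        "effector-memory": ["GZMK", "CXCR3", "KLRG1", "CD44", "EOMES"],
        "exhausted": ["TOX", "HAVCR2", "PDCD1", "CXCL13", "LAG3", "ENTPD1"],
    }


@dataclass(frozen=True)
class AggregateSpec:
    """Planted immune aggregate: class, size, composition, chemokine boost."""

    class_label: str
    n_cells: int
    composition: dict = field(default_factory=dict)   # cell type -> fraction
    cd8_state_mix: dict = field(default_factory=dict)  # state -> fraction
    chemokine_level: float = 1.0       # multiplies CXCL13/CXCR5 means
    radius_um: float = 40.0            # Gaussian sigma of member positions


def _default_aggregate_specs() -> list[AggregateSpec]:
    quiescent = dict(
        composition={"B": 0.10, "CD8 T": 0.45, "CD4 T": 0.25, "myeloid": 0.20},
        cd8_state_mix={"stem-like": 0.30, "effector": 0.40,
                       "effector-memory": 0.20, "exhausted": 0.10},
        chemokine_level=1.0,
    )
    stimulated = dict(
        composition={"B": 0.05, "CD8 T": 0.50, "CD4 T": 0.20, "myeloid": 0.25},
        cd8_state_mix={"stem-like": 0.05, "effector": 0.20,
                       "effector-memory": 0.05, "exhausted": 0.70},
        chemokine_level=1.0,
    )
    lymphoid = dict(
        composition={"B": 0.35, "CD8 T": 0.35, "CD4 T": 0.20, "myeloid": 0.10},
        cd8_state_mix={"stem-like": 0.60, "effector": 0.10,
                       "effector-memory": 0.20, "exhausted": 0.10},
        chemokine_level=4.0,
    )
    specs = []
    for cls, kw, sizes in (
        ("Quiescent", quiescent, (180, 220)),
        ("Stimulated", stimulated, (200, 160)),
        ("Lymphoid", lymphoid, (240, 200)),
    ):
        for n in sizes:
            specs.append(AggregateSpec(class_label=cls, n_cells=n, **kw))
    return specs


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic data generator.

    ``state_mixture`` gives the marginal CD8 state proportions;
    ``state_purity`` in [0, 1] shrinks the latent-coordinate spread within
    each state interval (0 = uniform over the interval, 1 = point mass at
    the interval center). ``clone_size_law`` is ``{"law": "geometric",
    "p": ...}`` or ``{"law": "zipf", "a": ...}``.
    """

    seed: int = 0
    n_cells: int = 2000
    gene_panel: tuple = DEFAULT_GENE_PANEL
    state_mixture: dict = field(default_factory=lambda: {
        "stem-like": 0.30, "effector": 0.25,
        "effector-memory": 0.20, "exhausted": 0.25,
    })
    nb_dispersion: float = 2.0
    zero_inflation: float = 0.10
    state_purity: float = 0.0
    expression_scale: float = 1.0  # multiplies all mean counts (sequencing depth)
    clone_size_law: dict = field(default_factory=lambda: {"law": "geometric", "p": 0.5})
    frac_expanding_with_stem: float = 0.477
    # tissue parameters
    tissue_width_um: float = 3000.0
    tissue_height_um: float = 3000.0
    aggregate_specs: tuple = field(default_factory=lambda: tuple(_default_aggregate_specs()))
    tumor_area_fraction: float = 0.25
    tumor_density_per_mm2: float = 250.0
    background_immune_density_per_mm2: float = 25.0
    tumor_overlap_tolerance: float = 0.10
    max_aggregate_retries: int = 200

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        missing = [g for g in REQUIRED_GENES if g not in self.gene_panel]
        if missing:
            raise ValueError(f"gene_panel missing required genes: {missing}")
        _check_mixture("state_mixture", self.state_mixture, allowed=set(STATES))
        for name, p in (("zero_inflation", self.zero_inflation),
                        ("frac_expanding_with_stem", self.frac_expanding_with_stem),
                        ("state_purity", self.state_purity)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be positive")
        if not self.expression_scale > 0:
            raise ValueError("expression_scale must be positive")
        law = self.clone_size_law.get("law")
        if law not in ("geometric", "zipf"):
            raise ValueError(f"clone_size_law.law must be geometric|zipf, got {law!r}")
        for spec in self.aggregate_specs:
            _check_mixture(f"aggregate composition ({spec.class_label})",
                           spec.composition)
            if spec.cd8_state_mix:
                _check_mixture(f"cd8_state_mix ({spec.class_label})",
                               spec.cd8_state_mix, allowed=set(STATES))
            if spec.n_cells <= 0:
                raise ValueError("aggregate n_cells must be positive")


def _check_mixture(name: str, mix: dict, allowed: set | None = None) -> None:
    if not mix:
        raise ValueError(f"{name} is empty")
    vals = np.array(list(mix.values()), dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError(f"{name} has proportions outside [0, 1]: {mix}")
    if abs(vals.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} proportions must sum to 1, got {vals.sum():.6f}")
    if allowed is not None:
        unknown = set(mix) - allowed
        if unknown:
            raise ValueError(f"{name} has unknown labels: {sorted(unknown)}")


def well_separated_config(seed: int = 0, n_cells: int = 2000) -> SimConfig:
    """Preset with concentrated states and low noise, for recoverability checks."""
    return SimConfig(
        seed=seed, n_cells=n_cells,
        state_mixture={s: 0.25 for s in STATES},
        nb_dispersion=15.0, zero_inflation=0.05, state_purity=0.85,
        expression_scale=5.0,
    )


def well_separated_tissue_config(seed: int = 0) -> SimConfig:
    """Tissue preset with widely spaced, internally pure aggregates."""
    return replace(well_separated_config(seed=seed),
                   background_immune_density_per_mm2=10.0)


@dataclass
class GroundTruth:
    """Latent truth recorded by the generator; fields are None when unused."""

    u: Optional[np.ndarray] = None                 # latent differentiation coord
    state_label: Optional[np.ndarray] = None       # per-cell true state
    aggregate_id: Optional[np.ndarray] = None      # per-cell (-1 = none)
    aggregate_class: Optional[pd.Series] = None    # per-aggregate class label
    aggregate_center: Optional[pd.DataFrame] = None
    clone_id: Optional[np.ndarray] = None
    clone_archetype: Optional[pd.Series] = None    # per-clone stem-maintained flag
    clone_sizes: Optional[pd.Series] = None


# --------------------------------------------------------------------------
# CD8 counts

def _sample_u(rng: np.random.Generator, states: np.ndarray, purity: float) -> np.ndarray:
    """Latent coordinate: uniform over the state's quarter-interval, shrunk
    toward the interval center by ``purity``."""
    centers = np.array([_STATE_CENTERS[s] for s in states])
    half_width = 0.125 * (1.0 - purity)
    return centers + rng.uniform(-half_width, half_width, size=states.size)


def _means_from_u(u: np.ndarray, panel: Sequence[str]) -> np.ndarray:
    """Per-cell mean vector: log-linear interpolation of state archetypes
    along u with knots at the state centers (constant beyond the ends)."""
    arch = archetype_means(panel)
    log_arch = np.log(arch.to_numpy())            # 4 x G
    uc = np.clip(u, _STATE_KNOTS[0], _STATE_KNOTS[-1])
    idx = np.clip(np.searchsorted(_STATE_KNOTS, uc, side="right") - 1, 0, 2)
    t = (uc - _STATE_KNOTS[idx]) / (_STATE_KNOTS[idx + 1] - _STATE_KNOTS[idx])
    logm = (1 - t)[:, None] * log_arch[idx] + t[:, None] * log_arch[idx + 1]
    return np.exp(logm)


def _sample_counts(rng: np.random.Generator, means: np.ndarray,
                   dispersion: float, zero_inflation: float) -> np.ndarray:
    """NB(mean, theta) counts with independent dropout; theta=inf -> Poisson."""
    if math.isinf(dispersion):
        counts = rng.poisson(means)
    else:
        p = dispersion / (dispersion + means)
        counts = rng.negative_binomial(dispersion, p)
    if zero_inflation > 0:
        counts = np.where(rng.random(means.shape) < zero_inflation, 0, counts)
    return counts.astype(np.int64)


def simulate_cd8_counts(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a CD8 cell-by-gene count matrix along the stem→exhausted axis.

    Returns a cells x genes integer DataFrame (index ``cell_id``) and the
    ground truth (latent u, true state labels).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    states_order = [s for s in STATES if s in config.state_mixture]
    probs = np.array([config.state_mixture[s] for s in states_order])
    states = rng.choice(np.array(states_order, dtype=object),
                        size=config.n_cells, p=probs)
    u = _sample_u(rng, states, config.state_purity)
    means = _means_from_u(u, config.gene_panel) * config.expression_scale
    counts = _sample_counts(rng, means, config.nb_dispersion, config.zero_inflation)
    cells = [f"cell{i:06d}" for i in range(config.n_cells)]
    mat = pd.DataFrame(counts, index=pd.Index(cells, name="cell_id"),
                       columns=list(config.gene_panel))
    truth = GroundTruth(u=u, state_label=states.astype(str))
    return mat, truth


# --------------------------------------------------------------------------
# Clonotypes

def _draw_clone_sizes(rng: np.random.Generator, law: dict, n_cells: int) -> np.ndarray:
    sizes = []
    total = 0
    while total < n_cells:
        block = 1024
        if law["law"] == "geometric":
            draw = rng.geometric(law.get("p", 0.5), size=block)
        else:
            draw = rng.zipf(law.get("a", 2.5), size=block)
        for s in draw:
            s = int(min(s, n_cells - total))
            sizes.append(s)
            total += s
            if total >= n_cells:
                break
    return np.array(sizes, dtype=np.int64)


def simulate_clonotypes(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Assign each cell a surrogate paired-chain clonotype string.

    Clone sizes follow ``clone_size_law``. Among clones of size >= 3
    ("expanding"), a fraction ``frac_expanding_with_stem`` is drawn to be
    stem-maintained and seeded with >= 2 stem-like cells; the rest receive
    none. Returns a DataFrame with columns cell_id, clonotype_id and
    records per-clone truth on ``truth``.
    """
    config.validate()
    if truth.state_label is None:
        raise ValueError("truth must carry per-cell state labels")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC10]))
    n = len(truth.state_label)
    sizes = _draw_clone_sizes(rng, config.clone_size_law, n)
    n_clones = sizes.size

    stem_pool = list(np.flatnonzero(truth.state_label == "stem-like"))
    other_pool = list(np.flatnonzero(truth.state_label != "stem-like"))
    rng.shuffle(stem_pool)
    rng.shuffle(other_pool)

    expanding = sizes >= 3
    stem_maintained = np.zeros(n_clones, dtype=bool)
    stem_maintained[expanding] = rng.random(int(expanding.sum())) < config.frac_expanding_with_stem

    clone_of_cell = np.full(n, -1, dtype=np.int64)
    # pass 1: seed stem-maintained clones with 2 stem cells each
    for c in np.flatnonzero(stem_maintained):
        take = min(2, len(stem_pool))
        for _ in range(take):
            clone_of_cell[stem_pool.pop()] = c
    # pass 2: non-stem-maintained expanding clones draw only from the
    # non-stem pool so their stem multiplicity stays <= 1 (0 in practice);
    # they are filled before the unbiased clones can deplete that pool
    filled = np.bincount(clone_of_cell[clone_of_cell >= 0], minlength=n_clones)

    def _fill(c: int, unbiased: bool) -> None:
        for _ in range(sizes[c] - filled[c]):
            if unbiased and stem_pool and other_pool:
                k = rng.integers(len(stem_pool) + len(other_pool))
                pool = stem_pool if k < len(stem_pool) else other_pool
            elif unbiased:
                pool = stem_pool if stem_pool else other_pool
            else:
                pool = other_pool if other_pool else stem_pool
            if not pool:
                return
            clone_of_cell[pool.pop()] = c
            filled[c] += 1

    for c in np.flatnonzero(expanding & ~stem_maintained):
        _fill(c, unbiased=False)
    for c in range(n_clones):
        _fill(c, unbiased=True)

    assigned = clone_of_cell >= 0
    clone_ids = np.array([f"TRA:{c:05d}|TRB:{c:05d}" for c in range(n_clones)])
    df = pd.DataFrame({
        "cell_id": [f"cell{i:06d}" for i in np.flatnonzero(assigned)],
        "clonotype_id": clone_ids[clone_of_cell[assigned]],
    })
    truth.clone_id = clone_of_cell
    truth.clone_archetype = pd.Series(
        np.where(stem_maintained, "stem-maintained", "exhaustion-dominant"),
        index=pd.Index(clone_ids, name="clonotype_id"), name="archetype")
    realized = pd.Series(np.bincount(clone_of_cell[assigned], minlength=n_clones),
                         index=pd.Index(clone_ids, name="clonotype_id"), name="size")
    truth.clone_sizes = realized
    return df


# --------------------------------------------------------------------------
# Tissue

_GRID = 96  # tumor-field resolution per axis


def _tumor_mask(rng: np.random.Generator, frac: float) -> np.ndarray:
    """Blob-shaped tumor regions: thresholded smoothed Gaussian noise."""
    fieldv = rng.normal(size=(_GRID, _GRID))
    smooth = ndimage.gaussian_filter(fieldv, sigma=6.0, mode="wrap")
    thr = np.quantile(smooth, 1.0 - frac)
    return smooth > thr


def _in_tumor(mask: np.ndarray, x: np.ndarray, y: np.ndarray,
              width: float, height: float) -> np.ndarray:
    ix = np.clip((x / width * _GRID).astype(int), 0, _GRID - 1)
    iy = np.clip((y / height * _GRID).astype(int), 0, _GRID - 1)
    return mask[iy, ix]


def simulate_tissue(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a tissue map with planted stromal immune aggregates.

    Returns ``(cell_map, counts, truth)`` where ``cell_map`` has columns
    cell_id, x_um, y_um, compartment, cell_type (+ true_state for CD8 cells)
    and ``counts`` is the matching cells x genes count matrix.
    """
    config.validate()
    if not config.aggregate_specs:
        raise ValueError("aggregate_specs must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x715]))
    W, H = config.tissue_width_um, config.tissue_height_um
    mask = _tumor_mask(rng, config.tumor_area_fraction)
    area_mm2 = (W / 1000.0) * (H / 1000.0)

    rows = []  # (x, y, compartment, cell_type, state, agg_id, chemokine)

    # tumor cells: homogeneous within tumor blobs (rejection sampling)
    n_tumor_target = rng.poisson(config.tumor_density_per_mm2 * area_mm2
                                 * config.tumor_area_fraction)
    n_have = 0
    while n_have < n_tumor_target:
        m = max(64, 4 * (n_tumor_target - n_have))
        xs = rng.uniform(0, W, m)
        ys = rng.uniform(0, H, m)
        keep = _in_tumor(mask, xs, ys, W, H)
        for x, y in zip(xs[keep], ys[keep]):
            if n_have >= n_tumor_target:
                break
            rows.append((x, y, "tumor", "tumor", None, -1, 1.0))
            n_have += 1

    # background immune cells scattered over stroma
    n_bg = rng.poisson(config.background_immune_density_per_mm2 * area_mm2)
    placed = 0
    while placed < n_bg:
        m = max(64, 4 * (n_bg - placed))
        xs = rng.uniform(0, W, m)
        ys = rng.uniform(0, H, m)
        keep = ~_in_tumor(mask, xs, ys, W, H)
        types = rng.choice(np.array(["B", "CD8 T", "CD4 T", "myeloid"], dtype=object),
                           size=m, p=[0.15, 0.35, 0.25, 0.25])
        for x, y, t in zip(xs[keep], ys[keep], types[keep]):
            if placed >= n_bg:
                break
            state = rng.choice(np.array(STATES, dtype=object)) if t == "CD8 T" else None
            rows.append((x, y, "stroma", t, state, -1, 1.0))
            placed += 1

    # planted aggregates: Gaussian clusters with centers in stroma
    centers = []
    agg_classes = []
    margin = 100.0
    for a, spec in enumerate(config.aggregate_specs):
        ok = False
        for _ in range(config.max_aggregate_retries):
            cx = rng.uniform(margin, W - margin)
            cy = rng.uniform(margin, H - margin)
            # probe circle at 2 sigma must mostly avoid tumor blobs
            ang = rng.uniform(0, 2 * np.pi, 32)
            rad = 2.0 * spec.radius_um * np.sqrt(rng.uniform(0, 1, 32))
            px = np.clip(cx + rad * np.cos(ang), 0, W - 1e-6)
            py = np.clip(cy + rad * np.sin(ang), 0, H - 1e-6)
            overlap = _in_tumor(mask, px, py, W, H).mean()
            too_close = any((cx - ox) ** 2 + (cy - oy) ** 2 < (8 * spec.radius_um) ** 2
                            for ox, oy in centers)
            if overlap <= config.tumor_overlap_tolerance and not too_close:
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place aggregate {a} ({spec.class_label}) outside "
                f"tumor regions after {config.max_aggregate_retries} retries")
        centers.append((cx, cy))
        agg_classes.append(spec.class_label)

        types = list(spec.composition)
        n_per_type = rng.multinomial(spec.n_cells, [spec.composition[t] for t in types])
        member_types = np.repeat(np.array(types, dtype=object), n_per_type)
        rng.shuffle(member_types)
        xs = np.clip(rng.normal(cx, spec.radius_um, spec.n_cells), 0, W - 1e-6)
        ys = np.clip(rng.normal(cy, spec.radius_um, spec.n_cells), 0, H - 1e-6)
        smix = spec.cd8_state_mix or {s: 0.25 for s in STATES}
        sord = list(smix)
        sp = np.array([smix[s] for s in sord])
        for x, y, t in zip(xs, ys, member_types):
            state = rng.choice(np.array(sord, dtype=object), p=sp) if t == "CD8 T" else None
            rows.append((x, y, "stroma", t, state, a, spec.chemokine_level))

    xs, ys, comps, ctypes, cstates, aggids, chem = map(np.array, zip(*rows))
    n = len(rows)
    cells = [f"tcell{i:06d}" for i in range(n)]

    # expression: CD8 cells follow state archetypes; others follow type profiles
    panel = list(config.gene_panel)
    arch = archetype_means(panel)
    means = np.empty((n, len(panel)))
    gidx = {g: j for j, g in enumerate(panel)}
    for i in range(n):
        if ctypes[i] == "CD8 T":
            mu = arch.loc[cstates[i]].to_numpy().copy()
        else:
            prof = _TYPE_PROFILES.get(ctypes[i], _TYPE_PROFILES["other"])
            mu = np.full(len(panel), prof["base"])
            for g, v in prof.items():
                if g in gidx:
                    mu[gidx[g]] = v
        lvl = chem[i]
        if lvl != 1.0:
            mu[gidx["CXCL13"]] *= lvl
            mu[gidx["CXCR5"]] *= lvl
        means[i] = mu * config.expression_scale
    counts = _sample_counts(rng, means, config.nb_dispersion, config.zero_inflation)

    cell_map = pd.DataFrame({
        "cell_id": cells, "x_um": xs.astype(float), "y_um": ys.astype(float),
        "compartment": comps, "cell_type": ctypes,
        "true_state": [s if s is not None else "" for s in cstates],
    })
    counts_df = pd.DataFrame(counts, index=pd.Index(cells, name="cell_id"),
                             columns=panel)
    truth = GroundTruth(
        state_label=np.array([s if s is not None else "" for s in cstates]),
        aggregate_id=aggids.astype(int),
        aggregate_class=pd.Series(agg_classes, name="class_label",
                                  index=pd.RangeIndex(len(agg_classes), name="aggregate_id")),
        aggregate_center=pd.DataFrame(centers, columns=["x_um", "y_um"]),
    )
    return cell_map, counts_df, truth
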