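"""Synthetic retinal mosaics and qPCR plates with the cohort's statistical structure.

The generator reproduces the features of real retinal maps that the
downstream statistics rely on:

* a hexagonal lattice clipped to an elliptical eye outline, sized to a
  target ommatidium count (700-950 per retina in the emulated cohort);
* a fixed dorsal rim band of DRA ommatidia (40 by default -- the DRA
  count is essentially invariant across retinas);
* an independent stochastic pale/yellow switch at every remaining site,
  with site probability

      pi(x, y) = logistic( logit(p0) + beta * exp(-d^2 / (2 s^2))
                           + gamma * a(x) ),

  where ``p0`` is the strain- and sex-specific base pale probability,
  ``beta`` (logit units) the amplitude of an optional Gaussian patch of
  elevated pale incidence centred at ``patch_center`` (fractions of the
  canvas) with spatial scale ``s`` px, and ``gamma`` a linear
  anterior->posterior gradient over a(x) in [-1, 1];
* a small rate ``unknown_rate`` of unscoreable ommatidia, relabelled
  uniformly at random after type assignment;
* an equator between the two central rows and a midline at the central
  column.

With ``beta = gamma = 0`` the marks are i.i.d. given the lattice, hence
exchangeable: this is the calibration condition for the join-count and
G-test type-I error studies.

Randomness contract: every generator takes one root seed; cohorts split
it into independent per-retina streams via ``numpy`` ``SeedSequence``
spawning.  Any change to the stream layout is a breaking change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mosaic_model import (
    DRA,
    OmmatidiumRecord,
    P_OC,
    RetinalMosaicMap,
    UNKNOWN,
    Y,
    hex_to_pixels,
)


class ParameterError(ValueError):
    """Synthetic-generation parameters are inconsistent or infeasible."""


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SyntheticRetinaParams:
    """Parameters of one synthetic retina (see module docstring)."""

    n_target: int = 800
    p0: float = 0.35
    patch_amplitude: float = 0.0  # beta, logit units
    patch_center: tuple[float, float] = (0.8, 0.8)  # canvas fractions (x, y)
    patch_sd: float = 450.0  # s, px
    ap_gradient: float = 0.0  # gamma, logit units over a(x) in [-1, 1]
    dra_count: int = 40
    ectopic_dra: int = 0
    unknown_rate: float = 0.005
    #: if True, the logit intercept is calibrated so the lattice-mean pale
    #: probability equals p0 even when patch/gradient modulation is on
    #: (cohort cells quote group-mean percentages, not base rates)
    p0_is_mean: bool = False
    canvas: tuple[float, float] = (1400.0, 1400.0)
    aspect: float = 1.1  # ellipse width/height ratio
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise ParameterError(f"p0 must be in (0,1), got {self.p0}")
        if not (0.0 <= self.unknown_rate < 1.0):
            raise ParameterError("unknown_rate must be in [0,1)")
        if self.dra_count > self.n_target:
            raise ParameterError("dra_count cannot exceed n_target")
        if self.n_target < 7:
            raise ParameterError("n_target too small for a retina")


@dataclass
class CohortCell:
    """One (strain, sex) cell of a cohort design."""

    species: str
    strain: str
    sex: str  # "F" | "M"
    p0: float
    n_target_mean: float
    n_target_sd: float
    replicates: int

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")


def zom4_like_params(
    n_target: int = 800, seed: int = 0, **overrides
) -> SyntheticRetinaParams:
    """Parameters emulating a ZOM4 male retina.

    The dorsal-posterior pale patch (1.5 logit, spatial scale ~450 px,
    centred at 80%/80% of the canvas) rides on a 0.6-logit
    anterior->posterior gradient; this geometry is calibrated so that
    synthetic ZOM4 retinas reproduce the strain's observed phenotype --
    near-universal global autocorrelation of the mosaic (reduced mixed
    joins) and a significantly pale-enriched posterior half.
    """
    kw = dict(
        n_target=n_target,
        p0=0.407,
        patch_amplitude=1.5,
        ap_gradient=0.6,
        p0_is_mean=True,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticRetinaParams(**kw)


@dataclass
class CohortDesign:
    """A cohort of synthetic retinas: one cell per (strain, sex)."""

    cells: list[CohortCell]
    seed: int = 0
    patch_amplitude_by_strain: dict[str, float] = field(default_factory=dict)
    ap_gradient_by_strain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cells:
            raise ParameterError("empty cohort design")

    @property
    def n_retinas(self) -> int:
        return sum(c.replicates for c in self.cells)


def default_cohort_design(seed: int = 0, patch: bool = True) -> CohortDesign:
    """The emulated 22-retina cohort: 4 strains x 2 sexes.

    Cell base pale probabilities are the cohort's observed group mean
    p+OC percentages; total-count means reproduce the observed ordering
    (TAM16 females largest, Oregon-R females smallest lab strain, males
    ~60 ommatidia below females).  ZOM4 carries the dorsal-posterior
    patch of elevated pale incidence (1.5 logit by default).
    """
    cells = [
        CohortCell("D. melanogaster", "Oregon-R", "F", 0.383, 762, 11, 3),
        CohortCell("D. melanogaster", "Oregon-R", "M", 0.293, 702, 11, 3),
        CohortCell("D. melanogaster", "Zi372", "F", 0.405, 800, 11, 2),
        CohortCell("D. melanogaster", "Zi372", "M", 0.315, 700, 11, 1),
        CohortCell("D. simulans", "ZOM4", "F", 0.443, 850, 20, 3),
        CohortCell("D. simulans", "ZOM4", "M", 0.407, 800, 20, 3),
        CohortCell("D. mauritiana", "TAM16", "F", 0.416, 924, 30, 3),
        CohortCell("D. mauritiana", "TAM16", "M", 0.296, 895, 30, 4),
    ]
    patches = {"ZOM4": 1.5} if patch else {}
    gradients = {"ZOM4": 0.6} if patch else {}
    return CohortDesign(
        cells=cells,
        seed=seed,
        patch_amplitude_by_strain=patches,
        ap_gradient_by_strain=gradients,
    )


def _hex_lattice_in_ellipse(
    n_target: int, canvas: tuple[float, float], aspect: float
) -> tuple[np.ndarray, float]:
    """Odd-r hex lattice sites inside a centred ellipse of ~n_target sites.

    Returns the (n, 2) array of (col, row) sites and the pixel pitch.
    The pitch is solved from the hex cell area (pitch^2 * sqrt(3)/2) that
    makes the ellipse hold n_target cells, then the lattice is clipped.
    """
    w, h = canvas
    # ellipse semi-axes: fill 90% of the canvas in the longer direction
    a = 0.45 * w
    b = a / aspect
    area = math.pi * a * b
    pitch = math.sqrt(area / n_target / (math.sqrt(3.0) / 2.0))
    n_rows = int(2 * b / (pitch * math.sqrt(3.0) / 2.0)) + 3
    n_cols = int(2 * a / pitch) + 3
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    cols = cols.ravel()
    rows = rows.ravel()
    x, y = hex_to_pixels(cols, rows, pitch)
    # centre the lattice block on the canvas centre
    x = x - (x.max() + x.min()) / 2 + w / 2
    y = y - (y.max() + y.min()) / 2 + h / 2
    inside = ((x - w / 2) / a) ** 2 + ((y - h / 2) / b) ** 2 <= 1.0
    sites = np.column_stack([cols[inside], rows[inside]])
    return sites, pitch


def generate_hex_retina(params: SyntheticRetinaParams) -> RetinalMosaicMap:
    """Generate one synthetic retinal mosaic map (deterministic given seed)."""
    rng = np.random.default_rng(params.seed)
    w, h = params.canvas
    sites, pitch = _hex_lattice_in_ellipse(params.n_target, params.canvas, params.aspect)
    cols = sites[:, 0]
    rows = sites[:, 1]
    x, y = hex_to_pixels(cols, rows, pitch)
    x = x - (x.max() + x.min()) / 2 + w / 2
    y = y - (y.max() + y.min()) / 2 + h / 2

    n = len(sites)
    types = np.empty(n, dtype=object)

    # DRA: contiguous dorsal band, filling rows top-down
    order = np.lexsort((cols, -rows))  # dorsal-most rows first
    if params.dra_count > n:
        raise ParameterError("dra_count exceeds available lattice sites")
    dra_idx = order[: params.dra_count]
    is_dra = np.zeros(n, dtype=bool)
    is_dra[dra_idx] = True
    if params.ectopic_dra:
        ventral = order[::-1][: params.ectopic_dra]
        is_dra[ventral] = True
    types[is_dra] = DRA

    # stochastic pale/yellow switch with optional regional modulation
    free = ~is_dra
    cx, cy = params.patch_center[0] * w, params.patch_center[1] * h
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    if x.max() > x.min():
        a_x = 2.0 * (x - x.min()) / (x.max() - x.min()) - 1.0
    else:  # pragma: no cover - degenerate single-column lattice
        a_x = np.zeros_like(x)
    modulation = (
        params.patch_amplitude * np.exp(-d2 / (2.0 * params.patch_sd**2))
        + params.ap_gradient * a_x
    )
    intercept = logit(params.p0)
    if params.p0_is_mean and np.ptp(modulation) > 0:
        from scipy.optimize import brentq

        intercept = brentq(
            lambda c: float(np.mean(logistic(c + modulation))) - params.p0,
            -30.0, 30.0, xtol=1e-12,
        )
    pi = logistic(intercept + modulation)
    if not np.all((pi > 0) & (pi < 1)):
        raise ParameterError("pale probability left (0,1) at some lattice site")
    pale = rng.random(n) < pi
    types[free & pale] = P_OC
    types[free & ~pale] = Y

    # unknowns: uniform relabelling of non-DRA sites, after type assignment
    if params.unknown_rate > 0:
        free_idx = np.flatnonzero(free)
        unk = free_idx[rng.random(len(free_idx)) < params.unknown_rate]
        types[unk] = UNKNOWN

    # equator between the two central occupied rows; midline at central column
    row_lo, row_hi = int(rows.min()), int(rows.max())
    equator = (row_lo + row_hi) / 2.0
    if equator == int(equator):
        equator += 0.5
    midline = int(round((cols.min() + cols.max()) / 2.0))

    recs = [
        OmmatidiumRecord(
            id=i, col=int(cols[i]), row=int(rows[i]),
            x=round(float(x[i]), 3), y=round(float(y[i]), 3), type=str(types[i]),
        )
        for i in range(n)
    ]
    meta = dict(params.metadata)
    meta.setdefault("seed", int(params.seed))
    return RetinalMosaicMap(
        ommatidia=recs,
        equator_boundary=float(equator),
        midline_col=int(midline),
        canvas=params.canvas,
        metadata=meta,
        pixel_pitch=pitch,
    )


def generate_cohort(design: CohortDesign) -> list[RetinalMosaicMap]:
    """One synthetic retina per replicate per (strain, sex) cell.

    Per-retina seeds are spawned from the design's root seed, so the
    cohort is reproducible as a whole and each retina individually.
    """
    root = np.random.SeedSequence(design.seed)
    streams = root.spawn(design.n_retinas)
    maps: list[RetinalMosaicMap] = []
    k = 0
    retina_id = 1
    for cell in design.cells:
        beta = design.patch_amplitude_by_strain.get(cell.strain, 0.0)
        gamma = design.ap_gradient_by_strain.get(cell.strain, 0.0)
        for _ in range(cell.replicates):
            ss = streams[k]
            k += 1
            cell_rng = np.random.default_rng(ss)
            n_target = max(
                100, int(round(cell_rng.normal(cell.n_target_mean, cell.n_target_sd)))
            )
            seed = int(ss.generate_state(1)[0] % (2**31))
            params = SyntheticRetinaParams(
                n_target=n_target,
                p0=cell.p0,
                patch_amplitude=beta,
                ap_gradient=gamma,
                p0_is_mean=True,
                seed=seed,
                metadata={
                    "species": cell.species,
                    "strain": cell.strain,
                    "sex": cell.sex,
                    "retina_id": retina_id,
                },
            )
            maps.append(generate_hex_retina(params))
            retina_id += 1
    return maps


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

GENES = ("rh3", "rh4", "rh5", "rh6")

#: Default per-(species, strain, sex) true index fractions (rh3 of rh3+rh4,
#: rh5 of rh5+rh6).  Strains with published index values use them; the
#: remaining strains are calibration choices preserving the observed
#: ordering (documented in the methods note).
DEFAULT_FRACTIONS: dict[tuple[str, str, str], dict[str, float]] = {
    ("D. melanogaster", "Oregon-R", "M"): {"rh3": 0.292, "rh5": 0.238},
    ("D. melanogaster", "Oregon-R", "F"): {"rh3": 0.290, "rh5": 0.207},
    ("D. melanogaster", "Zi372", "F"): {"rh3": 0.506, "rh5": 0.513},
    ("D. melanogaster", "Zi372", "M"): {"rh3": 0.429, "rh5": 0.416},
    ("D. melanogaster", "Zi86", "F"): {"rh3": 0.49, "rh5": 0.50},
    ("D. melanogaster", "Zi86", "M"): {"rh3": 0.43, "rh5": 0.41},
    ("D. simulans", "ZOM4", "F"): {"rh3": 0.489, "rh5": 0.589},
    ("D. simulans", "ZOM4", "M"): {"rh3": 0.444, "rh5": 0.528},
    ("D. simulans", "Tana10", "F"): {"rh3": 0.38, "rh5": 0.46},
    ("D. simulans", "Tana10", "M"): {"rh3": 0.33, "rh5": 0.40},
    ("D. simulans", "Kib32", "F"): {"rh3": 0.42, "rh5": 0.50},
    ("D. simulans", "Kib32", "M"): {"rh3": 0.38, "rh5": 0.45},
    ("D. mauritiana", "TAM16", "F"): {"rh3": 0.525, "rh5": 0.647},
    ("D. mauritiana", "TAM16", "M"): {"rh3": 0.511, "rh5": 0.531},
    ("D. mauritiana", "MAV1", "F"): {"rh3": 0.55, "rh5": 0.68},
    ("D. mauritiana", "MAV1", "M"): {"rh3": 0.53, "rh5": 0.57},
}


def fractions_with_sex_effect(
    delta_points: float,
    n_strains: int = 8,
    base_low: float = 0.30,
    base_high: float = 0.50,
) -> dict[tuple[str, str, str], dict[str, float]]:
    """Fractions for a simulation cohort with a known sex effect.

    Builds ``n_strains`` strains spread over three species, with male
    rh3/rh5 fractions evenly spaced in [base_low, base_high] and female
    fractions exactly ``delta_points``/100 higher -- so the true
    female-male index difference is ``delta_points`` on the percentage
    scale.  Used by parameter-recovery and type-I-error studies.
    """
    species = ["D. melanogaster", "D. simulans", "D. mauritiana"]
    bases = np.linspace(base_low, base_high, n_strains)
    out: dict[tuple[str, str, str], dict[str, float]] = {}
    for i, b in enumerate(bases):
        sp = species[i % 3]
        strain = f"sim{i:02d}"
        f_m = float(b)
        f_f = float(b + delta_points / 100.0)
        out[(sp, strain, "M")] = {"rh3": f_m, "rh5": f_m}
        out[(sp, strain, "F")] = {"rh3": f_f, "rh5": f_f}
    return out


@dataclass
class QpcrSimParams:
    """Simulation parameters for synthetic qPCR plates.

    ``fractions`` maps (species, strain, sex) to the true index fractions
    {"rh3": f3, "rh5": f5} with f in (0,1); relative template quantities
    are Q_rh3 = f3, Q_rh4 = 1-f3 and likewise for the rh5/rh6 pair.  Cq
    values follow

        Cq = C0 - log(Q) / log(E_g) + u_strain,g + u_rep,g + e_tech

    with gene-specific Gaussian strain and biological-replicate
    intercepts (sd ``sigma_strain`` / ``sigma_rep`` cycles) and
    independent technical noise (sd ``sigma_tech`` cycles).  Intercepts
    are drawn per gene so that they do not cancel identically from the
    expression indexes, mimicking gene-specific extraction and priming
    variation.
    """

    fractions: Mapping[tuple[str, str, str], Mapping[str, float]] = None
    sigma_strain: float = 0.25
    sigma_rep: float = 0.15
    sigma_tech: float = 0.12
    efficiencies: Mapping[str, float] = None
    n_bio_reps: int = 2
    n_tech_reps: int = 4
    baseline_cq: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fractions is None:
            self.fractions = dict(DEFAULT_FRACTIONS)
        if self.efficiencies is None:
            self.efficiencies = {g: 1.95 for g in GENES}
        for key, fr in self.fractions.items():
            for pair, f in fr.items():
                if not (0.0 < f < 1.0):
                    raise ParameterError(f"fraction {pair}={f} for {key} not in (0,1)")
        for g, e in self.efficiencies.items():
            if not (1.0 < e <= 2.0):
                raise ParameterError(f"efficiency {g}={e} not in (1, 2]")
        for s in (self.sigma_strain, self.sigma_rep, self.sigma_tech):
            if s < 0:
                raise ParameterError("noise sds must be >= 0")


def generate_qpcr_plates(params: QpcrSimParams) -> "QpcrDataset":
    """Simulate a long-format qPCR Cq table (deterministic given seed)."""
    from .qpcr_expression import QpcrDataset  # local import avoids a cycle

    rng = np.random.default_rng(params.seed)
    strains = sorted({k[1] for k in params.fractions})
    reps = [chr(ord("a") + i) for i in range(params.n_bio_reps)]
    u_strain = {
        (s, g): rng.normal(0.0, params.sigma_strain)
        for s in strains
        for g in GENES
    }
    u_rep = {
        (s, r, g): rng.normal(0.0, params.sigma_rep)
        for s in strains
        for r in reps
        for g in GENES
    }
    rows = []
    for (species, strain, sex), fr in sorted(params.fractions.items()):
        q = {
            "rh3": fr["rh3"],
            "rh4": 1.0 - fr["rh3"],
            "rh5": fr["rh5"],
            "rh6": 1.0 - fr["rh5"],
        }
        for r in reps:
            for g in GENES:
                e_g = params.efficiencies[g]
                base = (
                    params.baseline_cq
                    - math.log(q[g]) / math.log(e_g)
                    + u_strain[(strain, g)]
                    + u_rep[(strain, r, g)]
                )
                for t in range(1, params.n_tech_reps + 1):
                    cq = base + rng.normal(0.0, params.sigma_tech)
                    if not math.isfinite(cq):
                        raise ParameterError("non-finite Cq generated")
                    rows.append(
                        {
                            "species": species,
                            "strain": strain,
                            "sex": sex,
                            "bio_rep": r,
                            "gene": g,
                            "tech_rep": t,
                            "cq": cq,
                        }
                    )
    df = pd.DataFrame(rows)
    return QpcrDataset(data=df, efficiencies=dict(params.efficiencies))
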