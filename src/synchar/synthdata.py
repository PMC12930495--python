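"""Seeded synthetic fixtures: flow-cytometry event clouds, Hill dose-response
datasets on the standard 12-point inducer grids, and BsmBI-flanked DNA parts.

Every generator is a pure function of its spec: the same spec (including its
seed) reproduces byte-identical output, so fixtures never need to be shipped.

What is emulated, and what is not: fluorescence populations are log-normal
with log-normal scatter channels correlated as in singlet-dominated samples;
debris is a diffuse uniform cloud in log-scatter space. Real cytometry adds
instrument noise floors, compensation artifacts and multimodal expression
states that these clouds deliberately omit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flowproc import FLUOR, FSC_AREA, FSC_HEIGHT, EventTable
from .hillfit import DoseResponseDataset, HillParams, Mode, hill_response
from .seqcluster import (
    BSMBI,
    DEFAULT_ENZYMES,
    PartSequence,
    count_sites,
    reverse_complement,
)

#: 12-point inducer concentration grids used for sensor characterization
IPTG_GRID_UM = (0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 70.0, 100.0, 150.0, 200.0, 1000.0)
ARABINOSE_GRID_UM = (0.0, 10.0, 20.0, 50.0, 75.0, 100.0, 200.0, 500.0, 750.0, 1000.0, 2500.0, 5000.0)
ATC_GRID_PG_UL = (0.0, 1.0, 2.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 50.0, 100.0, 2000.0)

GRIDS = {"iptg": IPTG_GRID_UM, "arabinose": ARABINOSE_GRID_UM, "atc": ATC_GRID_PG_UL}


class GenerationError(RuntimeError):
    """Rejection sampling failed within the retry budget."""


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One log-normal fluorescence population."""

    log_mean: float
    log_sd: float
    weight: float = 1.0


@dataclass
class FlowSimSpec:
    """Synthetic cytometry sample: a mixture of log-normal fluorescence
    populations riding on correlated log-normal scatter channels, plus an
    optional diffuse debris fraction."""

    n_events: int = 10_000
    populations: tuple[Population, ...] = (Population(7.0, 0.5, 1.0),)
    scatter_log_mean: tuple[float, float] = (11.0, 10.6)  # (area, height)
    scatter_log_sd: float = 0.35
    scatter_corr: float = 0.9
    debris_fraction: float = 0.0
    debris_spread: float = 4.0  # half-width (in log units) of the debris cloud
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(p.weight for p in self.populations)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"population weights must sum to 1, got {w}")
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris fraction must be in [0, 1)")
        if not -1 < self.scatter_corr < 1:
            raise ValueError("scatter correlation must be in (-1, 1)")
        if self.n_events < 1:
            raise ValueError("need at least one event")


def simulate_flow(spec: FlowSimSpec) -> tuple[EventTable, np.ndarray]:
    """Draw one synthetic sample; returns the event table and the hidden
    per-event label (population index, or -1 for debris)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    n_debris = int(round(spec.debris_fraction * n))
    n_cells = n - n_debris

    weights = np.array([p.weight for p in spec.populations])
    labels_cells = rng.choice(len(spec.populations), size=n_cells, p=weights)
    log_fl = np.array([spec.populations[i].log_mean for i in labels_cells]) + np.array(
        [spec.populations[i].log_sd for i in labels_cells]
    ) * rng.standard_normal(n_cells)

    mu = np.array(spec.scatter_log_mean)
    s = spec.scatter_log_sd
    r = spec.scatter_corr
    cov = s**2 * np.array([[1.0, r], [r, 1.0]])
    log_scatter = rng.multivariate_normal(mu, cov, size=n_cells)

    # debris: diffuse, uncorrelated, dim
    deb_scatter = mu[None, :] - spec.debris_spread / 2 + spec.debris_spread * rng.random(
        (n_debris, 2)
    )
    deb_fl = (
        min(p.log_mean for p in spec.populations)
        - 2.0
        + rng.standard_normal(n_debris) * 1.0
    )

    area = np.concatenate([np.exp(log_scatter[:, 0]), np.exp(deb_scatter[:, 0])])
    height = np.concatenate([np.exp(log_scatter[:, 1]), np.exp(deb_scatter[:, 1])])
    fl = np.concatenate([np.exp(log_fl), np.exp(deb_fl)])
    labels = np.concatenate([labels_cells, -np.ones(n_debris, dtype=int)])

    perm = rng.permutation(n)
    df = pd.DataFrame(
        {FSC_AREA: area[perm], FSC_HEIGHT: height[perm], FLUOR: fl[perm]}
    )
    return EventTable(df, sample=f"sim-seed{spec.seed}"), labels[perm]


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseSimSpec:
    """Hill-curve medians on an inducer grid with multiplicative log-normal
    noise: y = f_theta(x) * exp(sigma * z), z ~ N(0, 1)."""

    theta: HillParams = field(
        default_factory=lambda: HillParams(y_max=3.0, y_min=0.01, n=2.0, k=40.0)
    )
    mode: Mode = "sensor"
    grid: tuple[float, ...] = IPTG_GRID_UM
    sigma: float = 0.1
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(g < 0) or np.any(np.diff(g) < 0):
            raise ValueError("grid must be non-negative and sorted")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_dose_response(spec: DoseSimSpec) -> tuple[DoseResponseDataset, HillParams]:
    """One record per grid point per replicate; sigma = 0 gives exact curve
    values. Returns the dataset and the generating truth theta*."""
    rng = np.random.default_rng(spec.seed)
    x = np.tile(np.asarray(spec.grid, dtype=float), spec.replicates)
    f = hill_response(x, spec.theta, spec.mode)
    y = f * np.exp(spec.sigma * rng.standard_normal(x.size))
    return DoseResponseDataset(x, y, spec.mode), spec.theta


# ---------------------------------------------------------------------------
# DNA parts
# ---------------------------------------------------------------------------

#: default entry-flank geometry: forward BsmBI site, 1-nt spacer, then the
#: 4-nt cloning overhang (mirrored on the 3' side)
DEFAULT_OVERHANG_PAIRS = (
    ("AATG", "GCTT"),
    ("GGAG", "TACT"),
    ("CCAT", "CGCT"),
    ("TGGC", "ACTA"),
)


@dataclass
class PartSimSpec:
    """Short random parts carrying BsmBI entry flanks and no internal sites
    for any of the three unloading enzymes."""

    n_parts: int = 30
    core_length_range: tuple[int, int] = (60, 200)
    overhang_pairs: tuple[tuple[str, str], ...] = DEFAULT_OVERHANG_PAIRS
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.core_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid core length range")
        if self.n_parts < 1:
            raise ValueError("need at least one part")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_part(name: str, core: str, overhangs: tuple[str, str]) -> PartSequence:
    """Assemble core + overhangs into a BsmBI entry-flanked part."""
    left, right = overhangs
    five = BSMBI.recognition + "A" * BSMBI.spacer_length + left
    three = right + "T" * BSMBI.spacer_length + reverse_complement(BSMBI.recognition)
    return PartSequence(name, five + core + three)


def _part_is_clean(part: PartSequence) -> bool:
    return count_sites(part.sequence, BSMBI) == 2 and all(
        count_sites(part.sequence, e) == 0 for e in DEFAULT_ENZYMES[1:]
    )


def simulate_parts(spec: PartSimSpec) -> list[PartSequence]:
    """Random-core parts; any candidate with stray recognition sites is
    rejected and redrawn (bounded retries)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.core_length_range
    parts: list[PartSequence] = []
    for i in range(spec.n_parts):
        overhangs = spec.overhang_pairs[i % len(spec.overhang_pairs)]
        for _ in range(spec.max_retries):
            core = _random_dna(rng, int(rng.integers(lo, hi + 1)))
            part = make_part(f"part{i + 1:03d}", core, overhangs)
            if _part_is_clean(part):
                parts.append(part)
                break
        else:
            raise GenerationError(
                f"could not generate a clean part within {spec.max_retries} retries"
            )
    return parts


def simulate_part_families(
    n_families: int = 3,
    parts_per_family: int = 5,
    core_length: int = 120,
    n_mutations: int = 4,
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[list[PartSequence], np.ndarray]:
    """Families of near-duplicate parts: each family derives from one random
    core template by a few point mutations, so within-family edit distances
    are far below between-family distances. Returns parts and family labels —
    a ground truth for clustering tests."""
    rng = np.random.default_rng(seed)
    parts: list[PartSequence] = []
    labels: list[int] = []
    pairs = DEFAULT_OVERHANG_PAIRS
    for fam in range(n_families):
        overhangs = pairs[fam % len(pairs)]
        for _ in range(max_retries):
            template = _random_dna(rng, core_length)
            if _part_is_clean(make_part("tmp", template, overhangs)):
                break
        else:
            raise GenerationError("could not generate a clean family template")
        for j in range(parts_per_family):
            for _ in range(max_retries):
                core = list(template)
                sites = rng.choice(core_length, size=n_mutations, replace=False)
                for s in sites:
                    core[s] = "ACGT"[rng.integers(4)]
                part = make_part(f"fam{fam + 1}_p{j + 1}", "".join(core), overhangs)
                if _part_is_clean(part):
                    parts.append(part)
                    labels.append(fam)
                    break
            else:
                raise GenerationError("could not generate a clean family member")
    return parts, np.array(labels)
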