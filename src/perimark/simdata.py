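"""Synthetic multi-tissue scRNA-seq counts and spatial sections with known
ground truth.

The generator emulates the statistical structure the marker-discovery
pipeline assumes: each tissue holds a pericyte population co-expressing the
two canonical mural markers (Cspg4/Pdgfrb by default), a confusable
smooth-muscle population expressing one of them, fibroblast/endothelial/
other backgrounds, and planted marker genes whose detection fractions
inside and outside pericytes are controlled exactly (``pi_in`` / ``pi_out``)
so the pipeline's percent-expressed filters have a known truth to recover.
Decoy markers with an intermediate detection rate are planted as negative
controls for the pct1 filter.

Counts follow a negative binomial (gamma-Poisson) with cell-type-specific
means, a shared dispersion, and lognormal library-size factors. Planted
marker and canonical-pair expression is Bernoulli-gated: an "on" draw is
1 + NB, so the empirical detection fraction equals the gate probability
exactly rather than being shrunk by NB zeros.

The spatial generator lays vessel-like self-avoiding artery paths, scattered
capillary spots, pericyte spots adjacent to capillaries, and background, on
a rectangular grid with 4-connectivity.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse

from .io import CountMatrix, GeneSetCollection

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SpotTruth",
    "ConfigurationError",
    "GenerationError",
    "simulate_tissue_counts",
    "simulate_multi_tissue",
    "simulate_spatial_section",
    "tissue_seed",
    "toy_gene_sets",
    "write_ground_truth",
]

REQUIRED_TYPES = ("pericyte", "smooth_muscle", "fibroblast", "endothelial", "other")
DEFAULT_TISSUES = ("lung", "heart", "kidney", "bladder")
SPATIAL_REGIONS = ("artery", "capillary", "pericyte", "background")

N_SIGNATURE_GENES = 40      # per-cell-type program block driving cluster separation
SIGNATURE_MEAN = 3.0        # NB mean of a program gene in its own type
SIGNATURE_BASELINE = 0.02   # and elsewhere
MARKER_ON_MEAN = 2.0        # extra counts (on top of the guaranteed 1) when gated on
LEAK_ON_MEAN = 0.3
CANONICAL_ON_MEAN = 2.0
SMC_SINGLE_MARKER_RATE = 0.7   # smooth muscle expresses marker_b at this rate
BACKGROUND_CANONICAL_RATE = 0.02


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """The requested structure cannot be generated (e.g. grid too small)."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    ``pi_in`` is the probability a planted marker is detected (count > 0) in
    a pericyte of its target tissue; ``pi_out`` the leak probability in any
    other cell. ``dual_pos_rate`` is the probability a pericyte co-expresses
    both canonical markers. ``nb_dispersion`` is the gamma-Poisson size
    parameter theta (variance = m + m^2/theta); ``libsize_lognormal`` gives
    (mu, sigma) of the log library-size factor.
    """

    n_tissues: int = 4
    n_cells: int | Sequence[int] = 600
    n_genes: int = 1200
    cell_type_proportions: dict[str, float] = field(default_factory=lambda: {
        "pericyte": 0.12,
        "smooth_muscle": 0.15,
        "fibroblast": 0.25,
        "endothelial": 0.20,
        "other": 0.28,
    })
    canonical_pair: tuple[str, str] = ("Cspg4", "Pdgfrb")
    n_planted_markers_per_tissue: int = 10
    n_shared_markers: int = 3
    n_decoys_per_tissue: int = 5
    decoy_pi_in: float = 0.5
    pi_in: float = 0.95
    pi_out: float = 0.01
    dual_pos_rate: float = 0.85
    nb_dispersion: float = 2.0
    libsize_lognormal: tuple[float, float] = (0.0, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [t for t in REQUIRED_TYPES if t not in self.cell_type_proportions]
        if missing:
            raise ConfigurationError(f"cell_type_proportions missing {missing}")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.cell_type_proportions.values()):
            raise ConfigurationError("proportions must be nonnegative")
        if not self.pi_in > self.pi_out:
            raise ConfigurationError(f"pi_in ({self.pi_in}) must exceed pi_out ({self.pi_out})")
        for name in ("n_tissues", "n_genes", "n_planted_markers_per_tissue"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        cells = self.cells_per_tissue()
        if any(c <= 0 for c in cells):
            raise ConfigurationError("n_cells must be positive")
        if self.n_shared_markers < 0 or self.n_decoys_per_tissue < 0:
            raise ConfigurationError("marker counts must be nonnegative")
        if self.n_shared_markers > self.n_planted_markers_per_tissue:
            raise ConfigurationError(
                f"n_shared_markers ({self.n_shared_markers}) exceeds the "
                f"per-tissue planted budget ({self.n_planted_markers_per_tissue})"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if len(self.canonical_pair) != 2 or self.canonical_pair[0] == self.canonical_pair[1]:
            raise ConfigurationError("canonical_pair must be two distinct gene IDs")

    def cells_per_tissue(self) -> list[int]:
        if isinstance(self.n_cells, (int, np.integer)):
            return [int(self.n_cells)] * self.n_tissues
        cells = [int(c) for c in self.n_cells]
        if len(cells) != self.n_tissues:
            raise ConfigurationError(
                f"n_cells has {len(cells)} entries for {self.n_tissues} tissues"
            )
        return cells

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        data = json.loads(Path(path).read_text())
        for key in ("canonical_pair", "libsize_lognormal"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted truth for one simulated tissue."""

    cell_tissue: list[str]
    cell_type: list[str]
    is_pericyte: np.ndarray
    planted_markers: dict[str, list[str]]          # tissue -> tissue-specific gene IDs
    shared_markers: dict[str, frozenset[str]]      # gene ID -> tissue membership
    decoy_markers: dict[str, list[str]]            # tissue -> decoy gene IDs
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.is_pericyte = np.asarray(self.is_pericyte, dtype=bool)
        universe = set(self.gene_ids)
        for tissue, genes in self.planted_markers.items():
            unknown = set(genes) - universe
            if unknown:
                raise ValueError(f"planted markers for {tissue} not in universe: {unknown}")
        if set(self.shared_markers) - universe:
            raise ValueError("shared markers not in gene universe")
        flags = np.array([t == "pericyte" for t in self.cell_type])
        if not np.array_equal(flags, self.is_pericyte):
            raise ValueError("is_pericyte flags inconsistent with cell-type labels")

    def markers_for(self, tissue: str) -> set[str]:
        """All genes planted as markers of ``tissue`` (specific + shared)."""
        out = set(self.planted_markers.get(tissue, []))
        out |= {g for g, members in self.shared_markers.items() if tissue in members}
        return out


@dataclass
class SpotTruth:
    """Region labels for a simulated spatial section."""

    region: dict[tuple[int, int], str]           # (row, col) -> region label
    artery_paths: list[list[tuple[int, int]]]

    def __post_init__(self) -> None:
        bad = set(self.region.values()) - set(SPATIAL_REGIONS)
        if bad:
            raise ValueError(f"unknown region labels {bad}")


def tissue_seed(master_seed: int, tissue: str) -> int:
    """Reproducible per-tissue seed: master + CRC32 of the label, mod 2^31."""
    return (int(master_seed) + zlib.crc32(tissue.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Gene universe layout
# ---------------------------------------------------------------------------

def _gene_universe(config: SimConfig, tissues: Sequence[str]) -> dict:
    """Deterministic gene universe shared across tissues.

    Layout: canonical pair, per-type signature blocks, per-tissue planted
    markers, shared markers, per-tissue decoys, background filler up to
    ``n_genes``.
    """
    a, b = config.canonical_pair
    names: list[str] = [a, b]
    signature: dict[str, list[str]] = {}
    for ctype in REQUIRED_TYPES:
        block = [f"sig_{ctype}_{i:02d}" for i in range(N_SIGNATURE_GENES)]
        signature[ctype] = block
        names.extend(block)
    n_specific = config.n_planted_markers_per_tissue
    planted: dict[str, list[str]] = {}
    for t in tissues:
        planted[t] = [f"mk_{t}_{i:02d}" for i in range(n_specific)]
        names.extend(planted[t])
    shared = [f"mkshared_{i:02d}" for i in range(config.n_shared_markers)]
    names.extend(shared)
    decoys: dict[str, list[str]] = {}
    for t in tissues:
        decoys[t] = [f"decoy_{t}_{i:02d}" for i in range(config.n_decoys_per_tissue)]
        names.extend(decoys[t])
    if len(names) > config.n_genes:
        raise ConfigurationError(
            f"n_genes={config.n_genes} too small for {len(names)} structured genes"
        )
    names.extend(f"g{i:04d}" for i in range(config.n_genes - len(names)))
    return {
        "names": names,
        "index": {g: i for i, g in enumerate(names)},
        "signature": signature,
        "planted": planted,
        "shared": shared,
        "decoys": decoys,
    }


def _shared_memberships(
    config: SimConfig, tissues: Sequence[str], shared: Sequence[str]
) -> dict[str, frozenset[str]]:
    """Tissue-membership sets for shared markers. The first shared marker
    spans the first two tissues (the lung/heart Higd1b analogue); the rest
    get seeded random subsets of size 2-3."""
    rng = np.random.default_rng(tissue_seed(config.seed, "shared-memberships"))
    memberships: dict[str, frozenset[str]] = {}
    for i, gene in enumerate(shared):
        if i == 0 and len(tissues) >= 2:
            memberships[gene] = frozenset(tissues[:2])
        else:
            size = int(rng.integers(2, min(3, len(tissues)) + 1))
            members = rng.choice(len(tissues), size=size, replace=False)
            memberships[gene] = frozenset(tissues[j] for j in members)
    return memberships


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and dispersion theta."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(theta, np.maximum(mean, 1e-12) / theta)
    out = rng.poisson(lam)
    out[mean <= 0] = 0
    return out


def _gated(rng: np.random.Generator, on: np.ndarray, on_mean: float, theta: float) -> np.ndarray:
    """Bernoulli-gated counts: off -> 0, on -> 1 + NB(on_mean).

    The +1 shift makes detection (count>0) an exact Bernoulli(`on` rate),
    which is what the percent-expressed filters are calibrated against.
    """
    counts = np.zeros(on.shape, dtype=np.int64)
    n_on = int(on.sum())
    if n_on:
        counts[on] = 1 + _nb(rng, np.full(n_on, on_mean), theta)
    return counts


def _simulate_counts(
    config: SimConfig,
    tissue_id: str,
    n_cells: int,
    universe: dict,
    memberships: dict[str, frozenset[str]],
    seed: int,
) -> tuple[CountMatrix, GroundTruth]:
    rng = np.random.default_rng(seed)
    names = universe["names"]
    index = universe["index"]
    n_genes = len(names)
    theta = config.nb_dispersion

    types = list(REQUIRED_TYPES)
    props = np.array([config.cell_type_proportions[t] for t in types])
    cell_type = rng.choice(types, size=n_cells, p=props / props.sum())
    is_peri = cell_type == "pericyte"

    mu, sigma = config.libsize_lognormal
    libfac = np.exp(rng.normal(mu, sigma, size=n_cells))

    # background baseline means, drawn once per tissue
    base = rng.gamma(2.0, 0.15, size=n_genes)
    mean = np.outer(base, libfac)  # genes x cells

    # signature programs separate the cell types in PC space
    for ctype, block in universe["signature"].items():
        rows = [index[g] for g in block]
        mean[rows, :] = SIGNATURE_BASELINE
        mask = cell_type == ctype
        if mask.any():
            mean[np.ix_(rows, mask)] = SIGNATURE_MEAN * libfac[mask]

    # structured genes are overwritten after the NB draw; zero their means
    a, b = config.canonical_pair
    structured = [index[a], index[b]]
    for t, genes in universe["planted"].items():
        structured.extend(index[g] for g in genes)
    structured.extend(index[g] for g in universe["shared"])
    for t, genes in universe["decoys"].items():
        structured.extend(index[g] for g in genes)
    mean[structured, :] = 0.0

    counts = _nb(rng, mean, theta)

    # canonical pair: exact dual-positive rate in pericytes; smooth muscle is
    # the confusable mural population expressing marker_b alone
    u = rng.random(n_cells)
    both = is_peri & (u < config.dual_pos_rate)
    rest = 1.0 - config.dual_pos_rate
    a_only = is_peri & ~both & (u < config.dual_pos_rate + rest / 3)
    b_only = is_peri & ~both & ~a_only & (u < config.dual_pos_rate + 2 * rest / 3)
    smc = cell_type == "smooth_muscle"
    other_bg = ~is_peri
    a_on = both | a_only | (other_bg & (rng.random(n_cells) < BACKGROUND_CANONICAL_RATE))
    b_on = both | b_only | (smc & (rng.random(n_cells) < SMC_SINGLE_MARKER_RATE))
    b_on |= other_bg & ~smc & (rng.random(n_cells) < BACKGROUND_CANONICAL_RATE)
    counts[index[a]] = _gated(rng, a_on, CANONICAL_ON_MEAN, theta)
    counts[index[b]] = _gated(rng, b_on, CANONICAL_ON_MEAN, theta)

    # planted markers / shared markers / decoys
    def plant(gene: str, p_in: float, p_out: float, active: bool) -> None:
        if active:
            on = np.where(is_peri, rng.random(n_cells) < p_in,
                          rng.random(n_cells) < p_out)
        else:
            on = rng.random(n_cells) < p_out
        counts[index[gene]] = _gated(
            rng, on, MARKER_ON_MEAN if active else LEAK_ON_MEAN, theta
        )

    for t, genes in universe["planted"].items():
        for g in genes:
            plant(g, config.pi_in, config.pi_out, active=(t == tissue_id))
    for g in universe["shared"]:
        plant(g, config.pi_in, config.pi_out, active=(tissue_id in memberships[g]))
    for t, genes in universe["decoys"].items():
        for g in genes:
            plant(g, config.decoy_pi_in, config.pi_out, active=(t == tissue_id))

    barcodes = [f"{tissue_id}_c{i:05d}" for i in range(n_cells)]
    matrix = CountMatrix(sparse.csr_matrix(counts), list(names), barcodes, tissue=tissue_id)
    truth = GroundTruth(
        cell_tissue=[tissue_id] * n_cells,
        cell_type=list(cell_type),
        is_pericyte=is_peri,
        planted_markers={t: list(g) for t, g in universe["planted"].items()},
        shared_markers=dict(memberships),
        decoy_markers={t: list(g) for t, g in universe["decoys"].items()},
        gene_ids=list(names),
    )
    return matrix, truth


def simulate_tissue_counts(
    config: SimConfig, tissue_id: str, seed: int
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate one tissue's gene x cell counts with planted truth.

    Deterministic given ``seed``. The gene universe covers all
    ``config.n_tissues`` tissues (default labels) so single- and multi-tissue
    outputs share gene IDs; markers of other tissues appear only at the leak
    rate here.
    """
    config.validate()
    tissues = _tissue_labels(config, extra=tissue_id)
    universe = _gene_universe(config, tissues)
    memberships = _shared_memberships(config, tissues, universe["shared"])
    n_cells = config.cells_per_tissue()[tissues.index(tissue_id)] \
        if tissue_id in tissues[: config.n_tissues] else config.cells_per_tissue()[0]
    return _simulate_counts(config, tissue_id, n_cells, universe, memberships, seed)


def _tissue_labels(config: SimConfig, extra: str | None = None) -> list[str]:
    labels = list(DEFAULT_TISSUES[: config.n_tissues])
    while len(labels) < config.n_tissues:
        labels.append(f"tissue{len(labels)}")
    if extra is not None and extra not in labels:
        labels[0] = extra
    return labels


def simulate_multi_tissue(
    config: SimConfig, seed: int
) -> dict[str, tuple[CountMatrix, GroundTruth]]:
    """Simulate all tissues over a shared gene universe.

    Per-tissue seeds derive reproducibly from the master seed; shared markers
    are planted in exactly their designated tissue subsets.
    """
    config.validate()
    if config.n_tissues < 2:
        raise ConfigurationError("simulate_multi_tissue requires n_tissues >= 2")
    tissues = _tissue_labels(config)
    universe = _gene_universe(config, tissues)
    memberships = _shared_memberships(config, tissues, universe["shared"])
    cells = config.cells_per_tissue()
    out: dict[str, tuple[CountMatrix, GroundTruth]] = {}
    for t, n_cells in zip(tissues, cells):
        out[t] = _simulate_counts(
            config, t, n_cells, universe, memberships, tissue_seed(seed, t)
        )
    return out


# ---------------------------------------------------------------------------
# Spatial section
# ---------------------------------------------------------------------------

SPATIAL_MARKERS = {
    "artery": "MYH11",
    "capillary": "PECAM1",
}
SPATIAL_PERICYTE_MARKERS = ("HIGD1B", "NOTCH3")
N_SPATIAL_PROGRAM = 24
N_SPATIAL_GENES = 200


def _spatial_universe(config: SimConfig) -> dict:
    a, b = (g.upper() for g in config.canonical_pair)
    names = [a, b, "MYH11", "PECAM1", "HIGD1B", "NOTCH3"]
    programs: dict[str, list[str]] = {}
    for region in ("artery", "capillary", "pericyte"):
        block = [f"PRG_{region.upper()}_{i:02d}" for i in range(N_SPATIAL_PROGRAM)]
        programs[region] = block
        names.extend(block)
    names.extend(f"G{i:04d}" for i in range(N_SPATIAL_GENES - len(names)))
    return {"names": names, "index": {g: i for i, g in enumerate(names)},
            "programs": programs, "canonical": (a, b)}


def _self_avoiding_path(
    rng: np.random.Generator, H: int, W: int, occupied: set[tuple[int, int]],
    target_len: int, max_tries: int = 200,
) -> list[tuple[int, int]]:
    """A 1-wide self-avoiding 4-connected path avoiding ``occupied``."""
    for _ in range(max_tries):
        side = rng.integers(4)
        if side == 0:
            pos = (0, int(rng.integers(W)))
        elif side == 1:
            pos = (H - 1, int(rng.integers(W)))
        elif side == 2:
            pos = (int(rng.integers(H)), 0)
        else:
            pos = (int(rng.integers(H)), W - 1)
        if pos in occupied:
            continue
        path = [pos]
        used = {pos}
        heading = None
        while len(path) < target_len:
            r, c = path[-1]
            moves = [(r + dr, c + dc) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
            moves = [m for m in moves
                     if 0 <= m[0] < H and 0 <= m[1] < W
                     and m not in used and m not in occupied]
            if not moves:
                break
            # weight continuing straight to keep the path vessel-like
            if heading is not None:
                straight = (r + heading[0], c + heading[1])
                weights = np.array([3.0 if m == straight else 1.0 for m in moves])
            else:
                weights = np.ones(len(moves))
            m = moves[int(rng.choice(len(moves), p=weights / weights.sum()))]
            heading = (m[0] - path[-1][0], m[1] - path[-1][1])
            path.append(m)
            used.add(m)
        if len(path) >= max(4, target_len // 2):
            return path
    raise GenerationError(
        f"could not place an artery path of length ~{target_len} on a {H}x{W} grid"
    )


def simulate_spatial_section(
    config: SimConfig,
    grid: tuple[int, int],
    seed: int,
    n_paths: int = 2,
    capillary_frac: float = 0.10,
    pericyte_adjacency_prob: float = 0.6,
    artery_marker_prob: float = 0.95,
    capillary_marker_prob: float = 0.95,
    pericyte_marker_prob: float = 0.8,
    coexpression_prob: float | None = None,
):
    """Simulate a spatial section on an ``(H, W)`` rectangular spot grid.

    Artery spots form connected 1-wide self-avoiding paths expressing the
    MYH11 analogue; capillary spots are scattered and express the PECAM1
    analogue; pericyte spots sit 4-adjacent to capillary spots and express
    both canonical genes (with ``coexpression_prob``, default the config's
    ``dual_pos_rate``) plus HIGD1B/NOTCH3 analogues; remaining spots are low
    uniform background. Returns ``(SpotTable, SpotTruth)``.
    """
    from .spatial import SpotTable  # local import: spatial does not import simdata

    H, W = grid
    if H < 8 or W < 8:
        raise GenerationError(f"grid {H}x{W} too small; need at least 8x8")
    if coexpression_prob is None:
        coexpression_prob = config.dual_pos_rate
    rng = np.random.default_rng(seed)
    universe = _spatial_universe(config)
    index = universe["index"]
    ca, cb = universe["canonical"]

    region: dict[tuple[int, int], str] = {}
    paths: list[list[tuple[int, int]]] = []
    occupied: set[tuple[int, int]] = set()
    for _ in range(n_paths):
        path = _self_avoiding_path(rng, H, W, occupied, target_len=(H + W) // 2)
        paths.append(path)
        occupied.update(path)
        for p in path:
            region[p] = "artery"

    free = [(r, c) for r in range(H) for c in range(W) if (r, c) not in region]
    cap_mask = rng.random(len(free)) < capillary_frac
    capillaries = [p for p, m in zip(free, cap_mask) if m]
    for p in capillaries:
        region[p] = "capillary"

    for r, c in capillaries:
        if rng.random() >= pericyte_adjacency_prob:
            continue
        neigh = [(r + dr, c + dc) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
        neigh = [m for m in neigh if 0 <= m[0] < H and 0 <= m[1] < W and m not in region]
        if neigh:
            region[neigh[int(rng.integers(len(neigh)))]] = "pericyte"

    coords = [(r, c) for r in range(H) for c in range(W)]
    for p in coords:
        region.setdefault(p, "background")

    n_spots = len(coords)
    n_genes = len(universe["names"])
    counts = np.zeros((n_genes, n_spots), dtype=np.int64)
    theta = config.nb_dispersion

    # background noise on filler genes only; named markers have no background
    filler = [i for g, i in index.items() if g.startswith("G")]
    counts[np.ix_(filler, range(n_spots))] = rng.poisson(0.15, size=(len(filler), n_spots))

    labels = np.array([region[p] for p in coords])
    for reg, block in universe["programs"].items():
        mask = labels == reg
        rows = [index[g] for g in block]
        if mask.any():
            on = rng.random((len(rows), int(mask.sum()))) < 0.9
            vals = np.where(on, 1 + rng.poisson(2.0, size=on.shape), 0)
            counts[np.ix_(rows, np.where(mask)[0])] = vals

    for reg, marker in SPATIAL_MARKERS.items():
        mask = labels == reg
        on = mask & (rng.random(n_spots) < (
            artery_marker_prob if reg == "artery" else capillary_marker_prob))
        counts[index[marker]] = _gated(rng, on, 2.0, theta)

    peri = labels == "pericyte"
    dual = peri & (rng.random(n_spots) < coexpression_prob)
    counts[index[ca]] = _gated(rng, dual, 2.0, theta)
    counts[index[cb]] = _gated(rng, dual, 2.0, theta)
    for marker in SPATIAL_PERICYTE_MARKERS:
        on = peri & (rng.random(n_spots) < pericyte_marker_prob)
        counts[index[marker]] = _gated(rng, on, 2.0, theta)

    barcodes = [f"spot_{r:03d}_{c:03d}" for r, c in coords]
    matrix = CountMatrix(
        sparse.csr_matrix(counts), list(universe["names"]), barcodes, tissue="spatial"
    )
    table = SpotTable(
        barcodes=barcodes,
        coords=np.array(coords, dtype=int),
        counts=matrix,
    )
    truth = SpotTruth(region=region, artery_paths=paths)
    return table, truth


# ---------------------------------------------------------------------------
# Convenience outputs
# ---------------------------------------------------------------------------

def toy_gene_sets(
    truth: GroundTruth,
    n_random: int = 9,
    random_set_size: int = 15,
    seed: int = 0,
) -> GeneSetCollection:
    """A small pathway collection for exercising GSEA on simulated data:
    one set per tissue built from its planted markers (these should enrich
    at the top of a pericyte-vs-rest ranking) plus seeded random sets."""
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for tissue in sorted(truth.planted_markers):
        members = truth.markers_for(tissue)
        if members:
            name = f"PLANTED_{tissue.upper()}"
            sets[name] = set(members)
            desc[name] = f"planted markers of {tissue}"
    genes = np.array(truth.gene_ids)
    for i in range(n_random):
        members = rng.choice(len(genes), size=random_set_size, replace=False)
        name = f"RANDOM_{i:02d}"
        sets[name] = {genes[j] for j in members}
        desc[name] = "random gene set"
    return GeneSetCollection(sets, desc)


def write_ground_truth(truth: GroundTruth, counts: CountMatrix, prefix: str | Path) -> None:
    """TSV of per-cell labels and JSON of planted marker sets."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("barcode\ttissue\tcell_type\tis_pericyte\n")
        for bc, ts, ct, flag in zip(
            counts.barcodes, truth.cell_tissue, truth.cell_type, truth.is_pericyte
        ):
            fh.write(f"{bc}\t{ts}\t{ct}\t{int(flag)}\n")
    payload = {
        "planted_markers": truth.planted_markers,
        "shared_markers": {g: sorted(m) for g, m in truth.shared_markers.items()},
        "decoy_markers": truth.decoy_markers,
    }
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2) + "\n")
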