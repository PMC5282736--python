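"""Synthetic character matrices and point clouds with planted structure.

Every stage of the disparity pipeline is testable against data whose truth
is known: groups of taxa are sampled from group-specific categorical
state-frequency profiles, a controllable fraction of characters is
diagnostic (different modal state) for each group, and missing /
inapplicable cells are overlaid at stated rates. Characters are generated
independently; no character-correlation model is imposed, matching the
independence assumption of the dissimilarity indices themselves.

Inapplicable cells are planted as a contiguous character block per taxon,
mimicking anatomical inapplicability (a suite of, say, limb characters
that cannot be scored in a limbless taxon), rather than independent
scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import INAPPLICABLE, MISSING, CharacterMatrix, TaxonGrouping

__all__ = [
    "SyntheticSpec",
    "generate_matrix",
    "generate_point_clouds",
    "lobopodian_preset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic character-matrix draw.

    ``divergence`` is the proportion of characters that are diagnostic for
    some group (its modal state is shifted for that group only); the
    diagnostic characters are shared out between groups round-robin, so
    every pair of groups differs in expectation. ``concentration`` is the
    probability mass on the modal state (the remainder spread uniformly),
    controlling within-group spread.
    """

    n_groups: int = 3
    taxa_per_group: int = 6
    n_characters: int = 40
    states_per_character: int = 2
    divergence: float = 0.5
    concentration: float = 0.85
    missing_rate: float = 0.1
    inapplicable_rate: float = 0.0
    n_outlier_taxa: int = 0
    outlier_missing_rate: float = 0.9
    group_names: tuple[str, ...] = field(default=())
    seed: int | None = None

    def __post_init__(self):
        if self.states_per_character < 2:
            raise ValueError("states_per_character must be >= 2")
        for name in ("divergence", "missing_rate", "inapplicable_rate",
                     "outlier_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.concentration <= 1.0:
            raise ValueError("concentration must lie in (0, 1]")
        if self.n_groups < 1 or self.taxa_per_group < 1:
            raise ValueError("need >= 1 group with >= 1 taxon")
        names = self.group_names or tuple(
            f"G{i + 1}" for i in range(self.n_groups)
        )
        if len(names) != self.n_groups:
            raise ValueError("group_names length must equal n_groups")
        object.__setattr__(self, "group_names", names)


def generate_matrix(
    spec: SyntheticSpec,
) -> tuple[CharacterMatrix, TaxonGrouping, dict]:
    """Draw a matrix, its true grouping and a truth record from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    m, s = spec.n_characters, spec.states_per_character

    base_modal = rng.integers(0, s, size=m)
    n_div = int(round(spec.divergence * m))
    diagnostic = rng.choice(m, size=n_div, replace=False)
    owner = {int(c): i % spec.n_groups for i, c in enumerate(diagnostic)}

    profiles = {}
    for g, name in enumerate(spec.group_names):
        modal = base_modal.copy()
        for c, og in owner.items():
            if og == g:
                modal[c] = (modal[c] + 1) % s
        profiles[name] = _profile(modal, s, spec.concentration)

    assignment: list[tuple[str, str]] = []
    for name in spec.group_names:
        for t in range(spec.taxa_per_group):
            assignment.append((f"{name}_{t + 1}", name))
    outliers = [f"outlier_{t + 1}" for t in range(spec.n_outlier_taxa)]
    base_profile = _profile(base_modal, s, spec.concentration)

    cells = []
    taxa = []
    for taxon, group in assignment:
        taxa.append(taxon)
        cells.append(
            _sample_row(profiles[group], rng, spec.missing_rate,
                        spec.inapplicable_rate)
        )
    for taxon in outliers:
        taxa.append(taxon)
        assignment.append((taxon, "outlier"))
        cells.append(
            _sample_row(base_profile, rng, spec.outlier_missing_rate, 0.0)
        )

    matrix = CharacterMatrix(taxa, cells, alphabet=range(s))
    grouping = TaxonGrouping(dict(assignment), spec.group_names)
    truth = {
        "spec": spec,
        "diagnostic_characters": {
            spec.group_names[g]: sorted(c for c, og in owner.items() if og == g)
            for g in range(spec.n_groups)
        },
        "outlier_taxa": outliers,
    }
    return matrix, grouping, truth


def _profile(modal: np.ndarray, s: int, concentration: float) -> np.ndarray:
    m = len(modal)
    probs = np.full((m, s), (1.0 - concentration) / (s - 1))
    probs[np.arange(m), modal] = concentration
    return probs


def _sample_row(
    probs: np.ndarray, rng, missing_rate: float, inapplicable_rate: float
) -> list:
    m, s = probs.shape
    states = (probs.cumsum(axis=1) > rng.random((m, 1))).argmax(axis=1)
    row: list = [int(x) for x in states]
    block = int(round(inapplicable_rate * m))
    if block > 0:
        start = int(rng.integers(0, m - block + 1))
        for j in range(start, start + block):
            row[j] = INAPPLICABLE
    if missing_rate > 0:
        mask = rng.random(m) < missing_rate
        for j in np.flatnonzero(mask):
            if row[j] is not INAPPLICABLE:
                row[j] = MISSING
    return row


# ----------------------------------------------------------------------
def generate_point_clouds(
    n_groups: int,
    n_points: int,
    dimension: int,
    centroid_separation: float,
    spread: float | np.ndarray = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Gaussian clouds at the vertices of a regular simplex.

    Centroids sit at a regular simplex scaled so pairwise centroid
    distance equals ``centroid_separation`` (requires
    ``dimension >= n_groups - 1``; in lower dimensions the simplex is
    truncated and the truth record carries the actual distances).
    ``spread`` is the per-group isotropic standard deviation (scalar or
    one value per group). Returns (coordinates, labels, truth).
    """
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(seed)
    spreads = np.broadcast_to(np.asarray(spread, dtype=float), (n_groups,))

    centroids = _simplex(n_groups, dimension) * centroid_separation
    coords, labels = [], []
    for g in range(n_groups):
        pts = centroids[g] + rng.standard_normal((n_points, dimension)) * spreads[g]
        coords.append(pts)
        labels.extend([g] * n_points)
    coords = np.vstack(coords)
    labels = np.array(labels)
    diff = centroids[:, None, :] - centroids[None, :, :]
    truth = {
        "centroids": centroids,
        "centroid_distances": np.sqrt((diff**2).sum(axis=2)),
        "spreads": spreads.copy(),
    }
    return coords, labels, truth


def _simplex(n: int, dimension: int) -> np.ndarray:
    """Vertices of a regular unit-edge simplex on ``n`` points, embedded
    (or truncated) into ``dimension`` axes and centred at the origin."""
    e = np.eye(n) / np.sqrt(2.0)  # pairwise distance 1
    e -= e.mean(axis=0)
    u, s, _ = np.linalg.svd(e, full_matrices=False)
    full = u[:, : n - 1] * s[: n - 1]
    out = np.zeros((n, dimension))
    k = min(dimension, n - 1)
    out[:, :k] = full[:, :k]
    return out


# ----------------------------------------------------------------------
def lobopodian_preset(seed: int | None = None):
    """Synthetic stand-in for a lobopodian disparity matrix (19 taxa x 39
    characters, three groups of interest plus intermediate taxa).

    This is generated data, not the published fossil matrix: it emulates
    the qualitative structure reported for total-group Onychophora (O),
    luolishaniids (L) and hallucigeniids (H) so the full pipeline can be
    exercised end-to-end. Planted structure:

    * O, L and H occupy distinct morphospace regions; L and H share the
      states of the characters diagnostic against O, so L and H are
      mutually closer than either is to O (phenograms join them).
    * H has the loosest state-frequency profile, hence the largest
      occupied hypervolume; L is intermediate, O tightest.
    * Three intermediate taxa are drawn from the H profile (two) and the
      L profile (one) but left outside the groups of interest, as targets
      for hypervolume inclusion tests.

    Returns (matrix, grouping, truth) like :func:`generate_matrix`.
    """
    rng = np.random.default_rng(seed)
    n_char = 39
    # a handful of multistate characters among a binary majority
    n_states = np.full(n_char, 2)
    n_states[[4, 9, 14, 19, 24, 29, 34]] = 3
    concentration = {
        "onychophora": 0.92,
        "luolishaniidae": 0.82,
        "hallucigeniidae": 0.75,
    }
    sizes = {"onychophora": 6, "luolishaniidae": 5, "hallucigeniidae": 5}
    # diagnostic blocks: O differs from (L, H) on 0-11; L alone on 12-19;
    # H alone on 20-27; 28-38 undiverged
    blocks = {
        "onychophora": range(0, 12),
        "luolishaniidae": range(12, 20),
        "hallucigeniidae": range(20, 28),
    }

    base_modal = np.array([rng.integers(0, s) for s in n_states])
    modal = {}
    for g in sizes:
        m = base_modal.copy()
        for c in blocks[g]:
            m[c] = (m[c] + 1) % n_states[c]
        modal[g] = m

    def profile(g):
        conc = concentration[g]
        probs = []
        for j in range(n_char):
            s = n_states[j]
            p = np.full(s, (1.0 - conc) / (s - 1))
            p[modal[g][j]] = conc
            probs.append(p)
        return probs

    profiles = {g: profile(g) for g in sizes}
    missing_rate, inapplicable_rate = 0.20, 0.05

    def sample(g):
        p = profiles[g]
        row = [int((np.cumsum(p[j]) > rng.random()).argmax())
               for j in range(n_char)]
        block = int(round(inapplicable_rate * n_char))
        start = int(rng.integers(0, n_char - block + 1))
        for j in range(start, start + block):
            row[j] = INAPPLICABLE
        for j in np.flatnonzero(rng.random(n_char) < missing_rate):
            if row[j] is not INAPPLICABLE:
                row[j] = MISSING
        return row

    taxa, cells, assignment = [], [], {}
    for g, n in sizes.items():
        for t in range(n):
            name = f"{g}_{t + 1}"
            taxa.append(name)
            assignment[name] = g
            cells.append(sample(g))
    intermediates = {
        "near_hallucigeniid_1": "hallucigeniidae",
        "near_hallucigeniid_2": "hallucigeniidae",
        "near_luolishaniid_1": "luolishaniidae",
    }
    for name, src in intermediates.items():
        taxa.append(name)
        assignment[name] = "intermediate"
        cells.append(sample(src))

    matrix = CharacterMatrix(
        taxa, cells, alphabet=range(int(n_states.max()))
    )
    grouping = TaxonGrouping(assignment, tuple(sizes))
    truth = {
        "concentration": concentration,
        "diagnostic_blocks": {g: list(b) for g, b in blocks.items()},
        "intermediate_sources": intermediates,
        "missing_rate": missing_rate,
        "inapplicable_rate": inapplicable_rate,
    }
    return matrix, grouping, truth
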