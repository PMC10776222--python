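"""Repertoire complexity indices on soft cluster memberships.

Three aspects of vocal complexity are quantified from the soft
clustering results:

* **gradation** — one value per vocal unit: the normalized effective
  number of clusters of its membership vector. 0 means the unit sits in
  a single cluster; 1 means it is equally attributable to all clusters.
* **diversity** — one value per individual: the same normalized
  effective number applied to the individual's *repertoire profile*,
  the arithmetic mean of the membership vectors of all its units.
* **overlap** — one value per pair of profiles: the Morisita–Horn
  index ``2 Σ x_i y_i / (Σ x_i² + Σ y_i²)``, the probability-weighted
  repertoire similarity (0 = disjoint clusters, 1 = identical
  distributions).

Effective numbers come in a Shannon form ``D1 = exp(−Σ p ln p)`` (all
clusters weighted equally) and a Simpson form ``D2 = 1/Σ p²`` (large
clusters dominate); both range over [1, K] and are mapped to [0, 1] by
``(D − 1)/(K − 1)``. ``D1 ≥ D2`` always, so the Shannon-normalized
index bounds the Simpson one from above on the same vector.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embed_cluster import NOISE, SoftMembership

_SIMPLEX_TOL = 1e-9


@dataclass
class RepertoireProfile:
    """Mean soft-membership vector of one individual (× unit type)."""

    individual: str
    unit_type: str  # call | song | all
    mean_probs: np.ndarray
    n_units: int
    sex: str = ""
    colony: str = ""

    def __post_init__(self) -> None:
        self.mean_probs = np.asarray(self.mean_probs, dtype=np.float64)
        _check_simplex(self.mean_probs)
        if self.n_units < 1:
            raise ValueError("profile needs at least one unit")

    @property
    def key(self) -> tuple[str, str]:
        return (self.individual, self.unit_type)


@dataclass
class IndexValue:
    value: float
    index_kind: str  # shannon | simpson
    scope: str  # unit_gradation | individual_diversity

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError(f"index value {self.value} outside [0, 1]")
        self.value = float(min(max(self.value, 0.0), 1.0))


@dataclass
class OverlapMatrix:
    """Pairwise Morisita–Horn values between repertoire profiles.

    Missing profile combinations hold NaN (marked missing, never zero);
    ``includes_self_cross`` flags call-vs-song matrices whose diagonal
    compares an individual's call profile with its own song profile.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    includes_self_cross: bool = False


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("expected a 1-D probability vector")
    if np.any(p < -_SIMPLEX_TOL):
        raise ValueError("probability vector has negative entries")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probability vector sums to {p.sum()}, not 1")
    return p


def effective_number_shannon(p: np.ndarray) -> float:
    """``D1 = exp(−Σ_{p_i>0} p_i ln p_i)`` — the effective number of
    equally common clusters under Shannon entropy. Ranges over [1, K]."""
    p = _check_simplex(p)
    pos = p[p > 0]
    return float(np.exp(-np.sum(pos * np.log(pos))))


def effective_number_simpson(p: np.ndarray) -> float:
    """``D2 = 1 / Σ p_i²`` — the inverse Simpson concentration."""
    p = _check_simplex(p)
    return float(1.0 / np.sum(p**2))


def normalize_diversity(d_eff: float, K: int) -> float:
    """Map an effective number in [1, K] linearly onto [0, 1].

    A vector concentrated on one cluster gives 0; the uniform vector
    gives 1. With a single cluster the index is degenerate and defined
    as 0 (warning).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        warnings.warn("K=1: diversity index degenerate, defined as 0", stacklevel=2)
        return 0.0
    if not 1.0 - 1e-9 <= d_eff <= K + 1e-9:
        raise ValueError(f"effective number {d_eff} outside [1, {K}]")
    return float(min(max((d_eff - 1.0) / (K - 1.0), 0.0), 1.0))


_EFFECTIVE = {"shannon": effective_number_shannon, "simpson": effective_number_simpson}


def unit_gradation(membership: SoftMembership, index_kind: str = "shannon") -> IndexValue:
    """Per-unit gradation: normalized effective cluster number of the
    unit's soft membership. Hard-assigned (one-hot) units score 0."""
    d_eff = _EFFECTIVE[index_kind](membership.probs)
    return IndexValue(
        value=normalize_diversity(d_eff, membership.K),
        index_kind=index_kind,
        scope="unit_gradation",
    )


def build_profile(
    memberships: list[SoftMembership],
    individual: str,
    unit_type: str = "all",
    sex: str = "",
    colony: str = "",
    include_noise: bool = True,
) -> RepertoireProfile:
    """Average the membership vectors of one individual's units.

    Noise-labelled units participate through their (uniform) soft
    vectors by default — dropping them would discard exactly the
    intermediate vocalizations soft clustering is meant to keep;
    ``include_noise=False`` restricts to hard-assigned units for
    sensitivity analyses.
    """
    if not include_noise:
        memberships = [m for m in memberships if m.hard_label != NOISE]
    if not memberships:
        raise ValueError(f"no units to build a profile for {individual!r}/{unit_type}")
    mean = np.mean([m.probs for m in memberships], axis=0)
    return RepertoireProfile(
        individual=individual,
        unit_type=unit_type,
        mean_probs=mean / mean.sum(),
        n_units=len(memberships),
        sex=sex,
        colony=colony,
    )


def individual_diversity(profile: RepertoireProfile, index_kind: str = "shannon") -> IndexValue:
    """Per-individual diversity: normalized effective cluster number of
    the repertoire profile."""
    K = profile.mean_probs.size
    d_eff = _EFFECTIVE[index_kind](profile.mean_probs)
    return IndexValue(
        value=normalize_diversity(d_eff, K),
        index_kind=index_kind,
        scope="individual_diversity",
    )


def morisita_horn(x: RepertoireProfile | np.ndarray, y: RepertoireProfile | np.ndarray) -> float:
    """Morisita–Horn overlap ``2 Σ x_i y_i / (Σ x_i² + Σ y_i²)``.

    1 iff the two distributions coincide; 0 iff their supports are
    disjoint. Symmetric and invariant to simultaneous cluster
    relabeling.
    """
    xv = np.asarray(x.mean_probs if isinstance(x, RepertoireProfile) else x, dtype=np.float64)
    yv = np.asarray(y.mean_probs if isinstance(y, RepertoireProfile) else y, dtype=np.float64)
    if xv.shape != yv.shape:
        raise ValueError("profiles must share the same cluster count")
    sx, sy = np.sum(xv**2), np.sum(yv**2)
    if sx == 0 or sy == 0:
        raise ValueError("zero profile vector")
    return float(2.0 * np.sum(xv * yv) / (sx + sy))


def overlap_matrices(profiles: list[RepertoireProfile]) -> dict[str, OverlapMatrix]:
    """All pairwise overlaps, per unit type plus the call-vs-song cross.

    ``call`` and ``song`` matrices are square and symmetric over the
    individuals having that profile type. ``call_vs_song`` has call
    profiles as rows and song profiles as columns over the union of
    individuals; its diagonal holds *self-similarities* (an
    individual's call profile vs its own song profile). Individuals
    missing a profile type yield NaN cells.
    """
    by_type: dict[str, dict[str, RepertoireProfile]] = {}
    for p in profiles:
        by_type.setdefault(p.unit_type, {})[p.individual] = p

    out: dict[str, OverlapMatrix] = {}
    for unit_type in ("call", "song"):
        inds = sorted(by_type.get(unit_type, {}))
        if len(inds) >= 2:
            m = np.full((len(inds), len(inds)), np.nan)
            for i, a in enumerate(inds):
                m[i, i] = 1.0
                for j in range(i + 1, len(inds)):
                    m[i, j] = m[j, i] = morisita_horn(
                        by_type[unit_type][a], by_type[unit_type][inds[j]]
                    )
            out[unit_type] = OverlapMatrix(values=m, row_labels=inds, col_labels=inds)

    calls, songs = by_type.get("call", {}), by_type.get("song", {})
    if calls and songs:
        inds = sorted(set(calls) | set(songs))
        m = np.full((len(inds), len(inds)), np.nan)
        for i, a in enumerate(inds):
            for j, b in enumerate(inds):
                if a in calls and b in songs:
                    m[i, j] = morisita_horn(calls[a], songs[b])
        out["call_vs_song"] = OverlapMatrix(
            values=m, row_labels=inds, col_labels=inds, includes_self_cross=True
        )
    return out


def heatmap_order(matrix: OverlapMatrix) -> list[int]:
    """Average-linkage hierarchical leaf order on 1 − overlap, for
    reproducing reordered heatmaps."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    vals = np.nan_to_num(matrix.values, nan=0.0)
    dist = 1.0 - (vals + vals.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return list(hierarchy.leaves_list(linkage))


def export_stats_tables(
    gradation_df: pd.DataFrame,
    diversity_df: pd.DataFrame,
    overlap_df: pd.DataFrame,
    out_dir,
) -> dict[str, str]:
    """Write the three tidy CSVs consumed by external statistics software.

    ``gradation_df``: one row per unit × index kind; ``diversity_df``:
    one row per individual × unit type × index kind; ``overlap_df``: one
    row per profile pair with within/between factor columns. Mandatory
    metadata columns are checked before writing.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = {
        "gradation": ["unit_id", "individual", "sex", "colony", "unit_type", "index_kind", "value"],
        "diversity": ["individual", "sex", "colony", "unit_type", "index_kind", "value"],
        "overlap": [
            "individual_a",
            "individual_b",
            "block",
            "sex_pair",
            "colony_pair",
            "index_kind",
            "value",
        ],
    }
    frames = {"gradation": gradation_df, "diversity": diversity_df, "overlap": overlap_df}
    paths = {}
    for name, df in frames.items():
        missing = [c for c in required[name] if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing column(s) {missing}")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths


def pair_factors(sex_a: str, sex_b: str, colony_a: str, colony_b: str) -> tuple[str, str]:
    """Factor coding for overlap pairs: sexes sorted alphabetically
    ("FF"/"FM"/"MM"), colony coded "within" or "between"."""
    return "".join(sorted((sex_a, sex_b))), "within" if colony_a == colony_b else "between"


def overlap_tidy_table(
    matrices: dict[str, OverlapMatrix],
    profiles: list[RepertoireProfile],
    index_kind: str = "morisita_horn",
) -> pd.DataFrame:
    """Flatten overlap matrices into one row per (unordered) pair.

    Within-type blocks enumerate unordered pairs; the call-vs-song block
    enumerates ordered (call individual, song individual) cells
    including self cells, flagged by ``is_self``.
    """
    meta = {p.individual: (p.sex, p.colony) for p in profiles}
    rows = []
    for block, mat in matrices.items():
        if block in ("call", "song"):
            pairs = itertools.combinations(range(len(mat.row_labels)), 2)
            cells = [(i, j) for i, j in pairs]
        else:
            cells = [
                (i, j)
                for i in range(len(mat.row_labels))
                for j in range(len(mat.col_labels))
                if np.isfinite(mat.values[i, j])
            ]
        for i, j in cells:
            a, b = mat.row_labels[i], mat.col_labels[j]
            if not np.isfinite(mat.values[i, j]):
                continue
            sex_a, col_a = meta.get(a, ("", ""))
            sex_b, col_b = meta.get(b, ("", ""))
            sex_pair, colony_pair = pair_factors(sex_a, sex_b, col_a, col_b)
            rows.append(
                {
                    "individual_a": a,
                    "individual_b": b,
                    "block": block,
                    "sex_pair": sex_pair,
                    "colony_pair": colony_pair,
                    "is_self": block == "call_vs_song" and a == b,
                    "index_kind": index_kind,
                    "value": float(mat.values[i, j]),
                }
            )
    return pd.DataFrame(rows)
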