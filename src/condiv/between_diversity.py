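"""Between-breed differentiation: Nei minimum distance, Weir-Cockerham Fst,
and a neighbor-joining tree on the distance matrix.

Nei's minimum distance between populations X and Y is

    DNei = (J_X + J_Y) / 2 - J_XY,

where ``J_X = mean_loci(p_X^2 + q_X^2)`` is the within-population allele
identity and ``J_XY = mean_loci(p_X p_Y + q_X q_Y)`` the between-population
identity.

Weir and Cockerham's theta is computed from the locus-wise variance
components (a, b, c) with observed sample sizes and heterozygosities, and
combined across loci as a ratio of sums.  The companion ``simple_fst`` is
the plain variance ratio ``sigma^2_p / (p_bar (1 - p_bar))`` with
unweighted means over populations; it ignores sampling corrections and is
bounded in [0, 1], while theta may dip slightly below zero at small sample
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, genotype_counts
from .within_diversity import breed_allele_freqs


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a zero diagonal."""

    breed_codes: list[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.breed_codes), len(self.breed_codes)):
            raise ValueError("matrix dimensions do not match breed list")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.breed_codes, columns=self.breed_codes)


def _freq_matrix(
    panel: GenotypePanel, breeds: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    breeds = breeds or panel.breed_codes
    return breeds, np.vstack([breed_allele_freqs(panel, b) for b in breeds])


def expected_identity(
    panel: GenotypePanel, breed: str, loci: np.ndarray | None = None
) -> float:
    """J: mean over loci of ``p^2 + (1-p)^2`` for one breed."""
    p = breed_allele_freqs(panel, breed)
    if loci is not None:
        p = p[loci]
    ok = ~np.isnan(p)
    if not ok.any():
        raise ValueError(f"breed {breed!r} has no usable loci")
    return float(np.mean(p[ok] ** 2 + (1 - p[ok]) ** 2))


def nei_minimum_distance(
    panel: GenotypePanel, x: str, y: str, loci: np.ndarray | None = None
) -> float:
    """Nei minimum distance between two breeds over shared called loci.

    ``loci`` optionally restricts the computation to a fixed set of variant
    indices (used to match the locus mask of a diversity partition).
    Non-negative by construction up to floating error; clipped at 0.
    """
    if x == y:
        return 0.0
    px = breed_allele_freqs(panel, x)
    py = breed_allele_freqs(panel, y)
    if loci is not None:
        px, py = px[loci], py[loci]
    ok = ~np.isnan(px) & ~np.isnan(py)
    if not ok.any():
        raise ValueError(f"breeds {x!r} and {y!r} share no called loci")
    px, py = px[ok], py[ok]
    jx = np.mean(px**2 + (1 - px) ** 2)
    jy = np.mean(py**2 + (1 - py) ** 2)
    jxy = np.mean(px * py + (1 - px) * (1 - py))
    return max(float((jx + jy) / 2 - jxy), 0.0)


def nei_distance_matrix(
    panel: GenotypePanel, breeds: list[str] | None = None, loci: np.ndarray | None = None
) -> DistanceMatrix:
    """Pairwise Nei minimum distances for all (given) breeds."""
    breeds = breeds or panel.breed_codes
    n = len(breeds)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_minimum_distance(panel, breeds[i], breeds[j], loci)
    return DistanceMatrix(list(breeds), d, "nei_minimum")


# ----------------------------------------------------------------------
# Weir-Cockerham theta
# ----------------------------------------------------------------------

def _wc_components(panel: GenotypePanel, breeds: list[str]):
    """Locus-wise Weir-Cockerham variance components (a, b, c).

    Only loci where every breed has >= 2 called genotypes enter; raises if
    none exists.
    """
    r = len(breeds)
    if r < 2:
        raise ValueError("theta needs at least two breeds")
    n_i, p_i, h_i = [], [], []
    for b in breeds:
        calls = panel.breed_calls(b)
        n_aa, n_ab, n_bb, _ = genotype_counts(calls)
        n_called = (n_aa + n_ab + n_bb).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2 * n_bb + n_ab) / (2 * n_called)
            h = n_ab / n_called
        n_i.append(n_called)
        p_i.append(p)
        h_i.append(h)
    n_i = np.vstack(n_i)  # (r, L)
    p_i = np.vstack(p_i)
    h_i = np.vstack(h_i)

    usable = (n_i >= 2).all(axis=0)
    if not usable.any():
        raise ValueError(
            "no locus with >= 2 called genotypes in every breed; "
            "cannot compute Weir-Cockerham theta"
        )
    n_i, p_i, h_i = n_i[:, usable], p_i[:, usable], h_i[:, usable]

    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def wc_fst_global(panel: GenotypePanel, breeds: list[str] | None = None) -> float:
    """Multi-breed, multi-locus theta (ratio of summed components)."""
    breeds = breeds or panel.breed_codes
    a, b, c = _wc_components(panel, breeds)
    denom = np.sum(a + b + c)
    if denom == 0:
        raise ValueError("all loci monomorphic; theta undefined")
    return float(np.sum(a) / denom)


def simple_fst(panel: GenotypePanel, breeds: list[str] | None = None) -> float:
    """Mean over loci of ``Var(p_i) / (p_bar (1 - p_bar))`` with unweighted
    per-breed frequencies; loci fixed across breeds are skipped."""
    breeds = breeds or panel.breed_codes
    _, freqs = _freq_matrix(panel, breeds)
    ok = ~np.isnan(freqs).any(axis=0)
    p = freqs[:, ok]
    p_bar = p.mean(axis=0)
    poly = (p_bar > 0) & (p_bar < 1)
    if not poly.any():
        raise ValueError("all loci fixed; simple Fst undefined")
    var = p[:, poly].var(axis=0)  # population variance across breeds
    return float(np.mean(var / (p_bar[poly] * (1 - p_bar[poly]))))


def wc_fst_pair(panel: GenotypePanel, x: str, y: str) -> tuple[float, float]:
    """Pairwise (theta, simple_fst) between two breeds."""
    return wc_fst_global(panel, [x, y]), simple_fst(panel, [x, y])


def fst_table(panel: GenotypePanel, breeds: list[str] | None = None) -> pd.DataFrame:
    """All pairwise theta / simple Fst values (long format)."""
    breeds = breeds or panel.breed_codes
    rows = []
    for i, x in enumerate(breeds):
        for y in breeds[i + 1 :]:
            theta, simple = wc_fst_pair(panel, x, y)
            rows.append({"breed_x": x, "breed_y": y, "theta": theta, "simple_fst": simple})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def neighbor_joining(matrix: DistanceMatrix | np.ndarray, labels: list[str] | None = None) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Deterministic: ties in the Q criterion are broken by the smallest pair
    of original taxon indices.  A negative branch length is clamped to zero
    with the deficit transferred to the branch of its sibling, preserving
    the distance between the joined nodes.  On an exactly additive matrix
    the generating tree (topology and branch lengths) is recovered.
    """
    if isinstance(matrix, DistanceMatrix):
        labels = matrix.breed_codes
        d = matrix.values.astype(float).copy()
    else:
        d = np.asarray(matrix, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    frags = list(labels)
    min_idx = list(range(n))  # smallest original taxon index under each node

    def join(i: int, j: int, li: float, lj: float) -> str:
        return f"({frags[i]}:{_fmt(li)},{frags[j]}:{_fmt(lj)})"

    while len(frags) > 3:
        m = len(frags)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((min_idx[i], min_idx[j])))
                if q < best_q - 1e-15 or (
                    abs(q - best_q) <= 1e-15 and best is not None and key < best[2]
                ):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        new_frag = join(i, j, li, lj)
        new_min = min(min_idx[i], min_idx[j])
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], d_new[keep]])
        d = np.column_stack([d, np.append(d_new[keep], 0.0)])
        frags = [frags[k] for k in keep] + [new_frag]
        min_idx = [min_idx[k] for k in keep] + [new_min]

    # resolve the final three nodes around a central vertex
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    lens = [la, lb, lc]
    for k in range(3):
        if lens[k] < 0:
            # transfer the deficit to the longest other branch (deterministic)
            other = max((kk for kk in range(3) if kk != k), key=lambda kk: (lens[kk], -kk))
            lens[other] += lens[k]
            lens[k] = 0.0
    return (
        f"({frags[0]}:{_fmt(lens[0])},{frags[1]}:{_fmt(lens[1])},"
        f"{frags[2]}:{_fmt(lens[2])});"
    )
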