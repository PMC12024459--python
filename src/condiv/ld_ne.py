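"""Linkage-disequilibrium decay and LD-based effective population size.

LD between two loci is measured as the squared Pearson correlation of
genotype dosages over the individuals called at both loci (composite LD;
no phasing required).  Binned mean r^2 against physical distance gives a
decay curve, which is inverted to an effective-size trajectory through the
drift expectation

    E[r^2] ~= 1 / (1 + 4 Ne c)  =>  Ne = (1 / (4 c)) (1 / r^2_adj - 1),

where ``c`` is the recombination fraction (Morgans) of the bin midpoint
under a constant recombination-rate map (default 1 cM/Mb), ``r^2_adj``
optionally subtracts the ``1/(2n)`` sampling inflation, and each bin maps
to ``t = 1/(2c)`` generations ago.  The map rate is the dominant source of
absolute Ne scale uncertainty; relative comparisons between breeds on the
same map are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .within_diversity import breed_allele_freqs


@dataclass
class LDCurve:
    """Binned r^2-vs-distance curve; empty bins are omitted."""

    breed_code: str
    bins: list[tuple[float, float, float, float, int]] = field(default_factory=list)
    # each bin: (lo_bp, hi_bp, midpoint_bp, mean_r2, n_pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bins, columns=["lo_bp", "hi_bp", "midpoint_bp", "mean_r2", "n_pairs"]
        )


@dataclass
class NeTrajectory:
    """Effective size against generations ago, one point per usable bin."""

    breed_code: str
    points: list[tuple[float, float]] = field(default_factory=list)  # (t, Ne)
    map_rate_cm_per_mb: float = 1.0
    sample_size_correction: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["generations_ago", "ne"])


def pairwise_r2(
    panel: GenotypePanel,
    breed: str,
    max_dist_bp: int = 1_000_000,
    max_pairs_per_chrom: int | None = None,
    seed: int = 0,
    min_obs: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """All (optionally subsampled) same-chromosome dosage r^2 values.

    Pairs are restricted to loci polymorphic within the breed, separated by
    at most ``max_dist_bp``; pairs with fewer than ``min_obs`` complete
    observations are skipped.  When a chromosome holds more candidate pairs
    than ``max_pairs_per_chrom``, a seeded uniform subsample is used.

    Returns ``(distances_bp, r2)`` arrays.
    """
    dos = panel.dosage(breed)  # (n_ind, n_variants) with NaN
    freqs = breed_allele_freqs(panel, breed)
    poly = (freqs > 0) & (freqs < 1)

    chrom = np.array([v.chromosome for v in panel.variants])
    pos = np.array([v.position_bp for v in panel.variants])
    rng = np.random.default_rng(seed)

    dist_out: list[np.ndarray] = []
    r2_out: list[np.ndarray] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero((chrom == c) & poly)
        if idx.size < 2:
            continue
        cpos = pos[idx]
        ii, jj = [], []
        for a in range(idx.size - 1):
            b_hi = np.searchsorted(cpos, cpos[a] + max_dist_bp, side="right")
            for b in range(a + 1, b_hi):
                ii.append(a)
                jj.append(b)
        if not ii:
            continue
        ii = np.asarray(ii)
        jj = np.asarray(jj)
        if max_pairs_per_chrom is not None and ii.size > max_pairs_per_chrom:
            pick = rng.choice(ii.size, size=max_pairs_per_chrom, replace=False)
            pick.sort()
            ii, jj = ii[pick], jj[pick]

        x = dos[:, idx[ii]]
        y = dos[:, idx[jj]]
        valid = ~np.isnan(x) & ~np.isnan(y)
        m = valid.sum(axis=0).astype(float)
        xv = np.where(valid, x, 0.0)
        yv = np.where(valid, y, 0.0)
        sx = xv.sum(axis=0)
        sy = yv.sum(axis=0)
        sxx = (xv * xv).sum(axis=0)
        syy = (yv * yv).sum(axis=0)
        sxy = (xv * yv).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = m * sxy - sx * sy
            varx = m * sxx - sx**2
            vary = m * syy - sy**2
            r2 = cov**2 / (varx * vary)
        ok = (m >= min_obs) & (varx > 0) & (vary > 0)
        dist_out.append((cpos[jj] - cpos[ii])[ok].astype(float))
        r2_out.append(r2[ok])

    if not dist_out:
        return np.empty(0), np.empty(0)
    return np.concatenate(dist_out), np.concatenate(r2_out)


def ld_decay_curve(
    pairs: tuple[np.ndarray, np.ndarray],
    bin_edges: np.ndarray,
    breed_code: str = "",
) -> LDCurve:
    """Bin pairwise r^2 by distance; bins with no pairs are omitted."""
    dist, r2 = np.asarray(pairs[0], float), np.asarray(pairs[1], float)
    if dist.size == 0:
        raise ValueError("no LD pairs to bin")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D array")
    which = np.digitize(dist, edges) - 1
    bins = []
    for k in range(edges.size - 1):
        sel = which == k
        n = int(sel.sum())
        if n == 0:
            continue
        bins.append(
            (
                float(edges[k]),
                float(edges[k + 1]),
                float((edges[k] + edges[k + 1]) / 2),
                float(r2[sel].mean()),
                n,
            )
        )
    return LDCurve(breed_code=breed_code, bins=bins)


def ne_from_ld(
    curve: LDCurve,
    map_rate_cm_per_mb: float = 1.0,
    mean_n: float | None = None,
    r2_floor: float = 1e-6,
) -> NeTrajectory:
    """Invert an LD curve to an Ne trajectory (one point per bin).

    ``mean_n`` enables the ``1/(2n)`` sampling correction; ``None`` turns
    it off.  Bins at zero distance are skipped.
    """
    if not curve.bins:
        raise ValueError("empty LD curve")
    points = []
    for lo, hi, mid, r2, n_pairs in curve.bins:
        c = mid * map_rate_cm_per_mb / 1e8  # Morgans
        if c <= 0:
            continue
        r2_adj = r2 - (1.0 / (2.0 * mean_n) if mean_n else 0.0)
        r2_adj = max(r2_adj, r2_floor)
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - 1.0)
        t = 1.0 / (2.0 * c)
        if ne > 0:
            points.append((t, ne))
    return NeTrajectory(
        breed_code=curve.breed_code,
        points=points,
        map_rate_cm_per_mb=map_rate_cm_per_mb,
        sample_size_correction=mean_n is not None,
    )
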