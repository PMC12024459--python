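"""Synthetic multi-breed SNP panels with known truth.

The generator emulates the structure of a livestock conservation panel: a
handful of closed breed populations genotyped on a medium-density chip.
Breed allele frequencies drift away from a shared ancestral frequency under
the Balding-Nichols model,

    p_breed ~ Beta(p (1 - F) / F, (1 - p)(1 - F) / F),

whose variance around the ancestral frequency ``p`` equals
``F p (1 - p)`` — i.e. ``F`` is the breed's target Fst.  Within a breed,
genotypes are drawn with an inbreeding coefficient ``F_ind``:

    P(bb) = p^2 + F_ind p (1 - p),   P(ab) = 2 p (1 - p)(1 - F_ind).

Loci are unlinked by default.  An optional linkage mode arranges loci in
blocks whose members are Markov copies of their neighbour, with a per-step
retention probability chosen so that adjacent-pair r^2 follows the drift
expectation ``1 / (1 + 4 Ne c)`` for a per-breed target effective size —
this plants a breed-specific LD decay signal for the LD/Ne estimators to
detect.

All randomness flows from one integer seed through per-breed substreams, so
the same configuration is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import MISSING, GenotypePanel, SampleRecord, VariantRecord


def default_chromosome_plan(
    n_snps: int, n_chromosomes: int = 28, length_bp: int = 50_000_000
) -> list[tuple[str, int, int]]:
    """Spread ``n_snps`` as evenly as possible over ``n_chromosomes``
    equally sized autosomes labelled "1".."n"."""
    base, extra = divmod(n_snps, n_chromosomes)
    plan = []
    for i in range(n_chromosomes):
        m = base + (1 if i < extra else 0)
        if m > 0:
            plan.append((str(i + 1), length_bp, m))
    return plan


@dataclass
class SimulationConfig:
    """Panel-generator settings.

    Defaults mirror a realistic conservation study: 16 breeds of ~20 birds
    each on tens of thousands of autosomal SNPs, moderate breed
    differentiation, and a low random missing-call rate.
    """

    n_breeds: int = 16
    samples_per_breed: int | Sequence[int] = 20
    n_snps: int = 20_000
    chromosome_plan: list[tuple[str, int, int]] | None = None
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    breed_fst: float | Sequence[float] = 0.15
    breed_inbreeding: float | Sequence[float] = 0.0
    missing_rate: float = 0.01
    seed: int | None = None
    breed_codes: Sequence[str] | None = None
    # linkage mode: block size 1 means unlinked loci
    ld_block_size: int = 1
    ld_target_ne: float | Sequence[float] | None = None
    map_rate_cm_per_mb: float = 1.0

    def _per_breed(self, value, name: str) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_breeds,)).copy()
        return arr

    def resolved(self) -> dict:
        """Validate and expand per-breed settings."""
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_breeds < 1 or self.n_snps < 1:
            raise ValueError("n_breeds and n_snps must be >= 1")
        n_samples = self._per_breed(self.samples_per_breed, "samples_per_breed").astype(int)
        if (n_samples < 1).any():
            raise ValueError("samples_per_breed must be >= 1")
        fst = self._per_breed(self.breed_fst, "breed_fst")
        if ((fst < 0) | (fst >= 1)).any():
            raise ValueError("breed_fst must lie in [0, 1)")
        f_ind = self._per_breed(self.breed_inbreeding, "breed_inbreeding")
        if ((f_ind < 0) | (f_ind > 1)).any():
            raise ValueError("breed_inbreeding must lie in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        law = self.ancestral_freq_law
        if law[0] not in ("uniform", "beta") or len(law) != 3:
            raise ValueError("ancestral_freq_law must be ('uniform', lo, hi) or ('beta', a, b)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.ld_block_size > 1:
            if self.ld_target_ne is None:
                raise ValueError("ld_target_ne is required when ld_block_size > 1")
            ne = self._per_breed(self.ld_target_ne, "ld_target_ne")
            if (ne <= 0).any():
                raise ValueError("ld_target_ne must be positive")
        else:
            ne = np.full(self.n_breeds, np.inf)
        codes = (
            list(self.breed_codes)
            if self.breed_codes is not None
            else [f"B{i + 1:02d}" for i in range(self.n_breeds)]
        )
        if len(codes) != self.n_breeds:
            raise ValueError("breed_codes length must equal n_breeds")
        plan = self.chromosome_plan or default_chromosome_plan(self.n_snps)
        if sum(m for _, _, m in plan) != self.n_snps:
            raise ValueError("chromosome_plan SNP counts must sum to n_snps")
        return {
            "n_samples": n_samples,
            "fst": fst,
            "f_ind": f_ind,
            "ne": ne,
            "codes": codes,
            "plan": plan,
        }


@dataclass
class SimulationTruth:
    """Ground truth of a simulated panel: ancestral and realized per-breed
    allele-b frequencies per variant, plus the generating configuration."""

    ancestral_freqs: np.ndarray  # (n_variants,)
    breed_freqs: np.ndarray  # (n_breeds, n_variants)
    breed_codes: list[str]
    config: SimulationConfig


def _draw_ancestral(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind, a, b = law
    if kind == "uniform":
        return rng.uniform(a, b, size)
    return rng.beta(a, b, size)


def _draw_genotypes(
    rng: np.random.Generator, p: np.ndarray, f_ind: float, n_ind: int
) -> np.ndarray:
    """Genotype matrix (n_ind x len(p)) under HW-with-inbreeding at freqs p."""
    p_bb = p**2 + f_ind * p * (1 - p)
    p_ab = 2 * p * (1 - p) * (1 - f_ind)
    u = rng.random((n_ind, p.size))
    return (2 * (u < p_bb) + ((u >= p_bb) & (u < p_bb + p_ab))).astype(np.int8)


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, SimulationTruth]:
    """Generate a multi-breed panel and its ground truth.

    Identical configurations (including the seed) produce bit-identical
    panels.  With ``breed_fst == 0`` the breed frequency equals the
    ancestral frequency exactly (no Beta draw).
    """
    res = config.resolved()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_breeds + 2)
    rng_global = np.random.default_rng(streams[0])
    rng_missing = np.random.default_rng(streams[1])

    # --- variant map: uniform positions per chromosome, sorted -----------
    variants: list[VariantRecord] = []
    chrom_slices: list[tuple[int, int]] = []  # variant index ranges per chromosome
    start = 0
    for label, length, m in res["plan"]:
        pos = np.sort(rng_global.integers(1, length + 1, size=m))
        for i in range(1, m):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        for k in range(m):
            j = start + k
            variants.append(VariantRecord(f"snp{j + 1:06d}", label, int(pos[k]), "A", "G"))
        chrom_slices.append((start, start + m))
        start += m
    n_snps = config.n_snps

    # --- block structure (linkage mode) ---------------------------------
    k_block = config.ld_block_size
    blocks: list[np.ndarray] = []  # variant indices per block (within one chromosome)
    for lo, hi in chrom_slices:
        for b0 in range(lo, hi, k_block):
            blocks.append(np.arange(b0, min(b0 + k_block, hi)))
    core_of = np.empty(n_snps, dtype=int)  # block index per variant
    for bi, idx in enumerate(blocks):
        core_of[idx] = bi
    n_blocks = len(blocks)

    # --- frequencies: one ancestral / breed frequency per block ----------
    p_core = _draw_ancestral(rng_global, config.ancestral_freq_law, n_blocks)
    ancestral = p_core[core_of]

    codes = res["codes"]
    breed_freqs = np.empty((config.n_breeds, n_snps))
    calls = np.empty((int(res["n_samples"].sum()), n_snps), dtype=np.int8)
    samples: list[SampleRecord] = []
    positions = np.array([v.position_bp for v in variants])

    row = 0
    for b in range(config.n_breeds):
        rng_b = np.random.default_rng(streams[2 + b])
        fst = res["fst"][b]
        if fst == 0:
            q_core = p_core.copy()
        else:
            q_core = rng_b.beta(p_core * (1 - fst) / fst, (1 - p_core) * (1 - fst) / fst)
        q = q_core[core_of]
        breed_freqs[b] = q
        n_ind = int(res["n_samples"][b])
        g = _draw_genotypes(rng_b, q, res["f_ind"][b], n_ind)
        if k_block > 1:
            fresh = _draw_genotypes(rng_b, q, res["f_ind"][b], n_ind)
            u = rng_b.random((n_ind, n_snps))
            ne = res["ne"][b]
            for idx in blocks:
                for j0, j1 in zip(idx[:-1], idx[1:]):
                    c_step = (
                        (positions[j1] - positions[j0])
                        * config.map_rate_cm_per_mb
                        / 1e8
                    )
                    rho = np.sqrt(1.0 / (1.0 + 4.0 * ne * c_step))
                    keep = u[:, j1] < rho
                    g[:, j1] = np.where(keep, g[:, j0], fresh[:, j1])
        calls[row : row + n_ind] = g
        samples.extend(
            SampleRecord(f"{codes[b]}_{i + 1:03d}", codes[b]) for i in range(n_ind)
        )
        row += n_ind

    if config.missing_rate > 0:
        mask = rng_missing.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    panel = GenotypePanel(samples, variants, calls)
    truth = SimulationTruth(ancestral, breed_freqs, list(codes), config)
    return panel, truth


def make_toy_panel() -> GenotypePanel:
    """A fixed 3-breed x 4-sample x 6-variant panel for hand enumeration.

    Genotype columns per breed (code of allele b, ``.`` = missing)::

        variant   v1 v2 v3 v4 v5 v6        (v1-v3 on chr 1, v4-v6 on chr 2)
        RED       0  0  1  0  2  0
                  1  0  1  0  2  1
                  1  0  1  1  2  2
                  2  0  1  1  2  .
        BLU       2  2  0  2  2  0
                  2  2  0  1  2  0
                  1  2  0  1  2  1
                  1  2  0  0  2  1
        GRN       1  0  0  0  1  1
                  1  1  0  0  2  1
                  1  1  1  0  2  1
                  1  2  2  0  2  1

    Allele-b frequencies, Ho, He, MAF, Nei distances and allele counts are
    all enumerable by hand; the expected per-breed summary ships with the
    test fixtures.
    """
    variants = [
        VariantRecord("v1", "1", 100, "A", "G"),
        VariantRecord("v2", "1", 200, "C", "T"),
        VariantRecord("v3", "1", 300, "A", "C"),
        VariantRecord("v4", "2", 150, "G", "T"),
        VariantRecord("v5", "2", 250, "A", "G"),
        VariantRecord("v6", "2", 350, "C", "G"),
    ]
    rows = {
        "RED": [
            [0, 0, 1, 0, 2, 0],
            [1, 0, 1, 0, 2, 1],
            [1, 0, 1, 1, 2, 2],
            [2, 0, 1, 1, 2, MISSING],
        ],
        "BLU": [
            [2, 2, 0, 2, 2, 0],
            [2, 2, 0, 1, 2, 0],
            [1, 2, 0, 1, 2, 1],
            [1, 2, 0, 0, 2, 1],
        ],
        "GRN": [
            [1, 0, 0, 0, 1, 1],
            [1, 1, 0, 0, 2, 1],
            [1, 1, 1, 0, 2, 1],
            [1, 2, 2, 0, 2, 1],
        ],
    }
    fao = {"RED": "native", "BLU": "native", "GRN": "adapted"}
    origin = {"RED": "government", "BLU": "private", "GRN": "university"}
    samples = []
    calls = []
    for code, mat in rows.items():
        for i, row in enumerate(mat):
            samples.append(SampleRecord(f"{code}_{i + 1}", code, fao[code], origin[code]))
            calls.append(row)
    return GenotypePanel(samples, variants, np.array(calls, dtype=np.int8))
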