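"""Core genotype-panel containers.

A :class:`GenotypePanel` holds diploid, biallelic genotype calls for a set
of samples that belong to labelled breed populations.  Calls are coded per
variant against an (arbitrary) reference allele ``allele_a``:

====  =========================
code  genotype
====  =========================
0     allele_a / allele_a
1     allele_a / allele_b
2     allele_b / allele_b
-1    missing (no call)
====  =========================

Every statistic downstream of the panel is symmetric in the two alleles, so
the orientation of the coding never affects results; it only matters for
file round trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Genotype code for a missing call.
MISSING: int = -1

FAO_CLASSES = frozenset({"native", "adapted"})
ORIGINS = frozenset({"government", "private", "university"})


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP: identifier, map position and the two alleles."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"{self.snp_id}: chromosome label must be non-empty")
        if self.position_bp < 1:
            raise ValueError(
                f"{self.snp_id}: position_bp must be >= 1, got {self.position_bp}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: allele_a and allele_b must differ")


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual with its breed assignment.

    ``fao_class`` ("native"/"adapted") and ``origin``
    ("government"/"private"/"university") are optional management metadata;
    ``None`` means not recorded.
    """

    sample_id: str
    breed_code: str
    fao_class: str | None = None
    origin: str | None = None

    def __post_init__(self) -> None:
        if not self.breed_code:
            raise ValueError(f"{self.sample_id}: breed_code must be non-empty")
        if self.fao_class is not None and self.fao_class not in FAO_CLASSES:
            raise ValueError(
                f"{self.sample_id}: fao_class must be one of {sorted(FAO_CLASSES)} "
                f"or None, got {self.fao_class!r}"
            )
        if self.origin is not None and self.origin not in ORIGINS:
            raise ValueError(
                f"{self.sample_id}: origin must be one of {sorted(ORIGINS)} "
                f"or None, got {self.origin!r}"
            )


class GenotypePanel:
    """Samples x variants matrix of genotype codes with breed labels.

    Parameters
    ----------
    samples
        Ordered sample records; ``sample_id`` must be unique.
    variants
        Ordered variant records; within each chromosome, records must be
        sorted by ``position_bp``.
    calls
        Integer matrix of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2, MISSING}``.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        variants: Sequence[VariantRecord],
        calls: np.ndarray,
    ) -> None:
        self.samples: list[SampleRecord] = list(samples)
        self.variants: list[VariantRecord] = list(variants)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2 or calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"calls contain {bad.sum()} entries outside {{0,1,2,{MISSING}}}")
        self.calls: np.ndarray = calls

        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique within a panel")

        # per-chromosome sort invariant
        last_pos: dict[str, int] = {}
        for v in self.variants:
            prev = last_pos.get(v.chromosome)
            if prev is not None and v.position_bp < prev:
                raise ValueError(
                    f"variants on chromosome {v.chromosome} are not sorted by "
                    f"position ({v.snp_id} at {v.position_bp} after {prev})"
                )
            last_pos[v.chromosome] = v.position_bp

        self._breed_index: dict[str, np.ndarray] = {}
        order: list[str] = []
        seen: set[str] = set()
        for s in self.samples:
            if s.breed_code not in seen:
                seen.add(s.breed_code)
                order.append(s.breed_code)
        labels = np.array([s.breed_code for s in self.samples])
        for code in order:
            self._breed_index[code] = np.flatnonzero(labels == code)
        self._breed_order = order

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def breed_codes(self) -> list[str]:
        """Breed codes in order of first appearance."""
        return list(self._breed_order)

    def sample_indices(self, breed_code: str) -> np.ndarray:
        """Row indices of the samples belonging to ``breed_code``."""
        try:
            return self._breed_index[breed_code]
        except KeyError:
            raise KeyError(f"unknown breed code {breed_code!r}") from None

    def breed_calls(self, breed_code: str) -> np.ndarray:
        """Genotype sub-matrix (samples of one breed x all variants)."""
        return self.calls[self.sample_indices(breed_code), :]

    def dosage(self, breed_code: str | None = None) -> np.ndarray:
        """Float genotype matrix with missing calls as NaN."""
        sub = self.calls if breed_code is None else self.breed_calls(breed_code)
        out = sub.astype(float)
        out[sub == MISSING] = np.nan
        return out

    # ------------------------------------------------------------------
    def subset(
        self,
        sample_idx: Iterable[int] | None = None,
        variant_idx: Iterable[int] | None = None,
    ) -> "GenotypePanel":
        """New panel restricted to the given sample/variant positions."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(list(sample_idx))
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(list(variant_idx))
        return GenotypePanel(
            [self.samples[i] for i in si],
            [self.variants[j] for j in vi],
            self.calls[np.ix_(si, vi)],
        )

    def flipped(self, variant_idx: Iterable[int] | None = None) -> "GenotypePanel":
        """Panel with the allele coding reversed at the given variants.

        Swaps ``allele_a``/``allele_b`` and maps codes 0<->2 (missing calls
        are untouched).  Used to assert that statistics are invariant under
        the arbitrary coding orientation.
        """
        vi = range(self.n_variants) if variant_idx is None else list(variant_idx)
        flip = np.zeros(self.n_variants, dtype=bool)
        flip[list(vi)] = True
        calls = self.calls.copy()
        cols = calls[:, flip]
        swapped = np.where(cols == MISSING, MISSING, 2 - cols)
        calls[:, flip] = swapped
        variants = [
            VariantRecord(v.snp_id, v.chromosome, v.position_bp, v.allele_b, v.allele_a)
            if flip[j]
            else v
            for j, v in enumerate(self.variants)
        ]
        return GenotypePanel(self.samples, variants, calls)

    # ------------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypePanel({self.n_samples} samples, {self.n_variants} variants, "
            f"{len(self._breed_order)} breeds)"
        )


def genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant counts ``(n_aa, n_ab, n_bb, n_missing)`` for a call matrix."""
    n_aa = (calls == 0).sum(axis=0)
    n_ab = (calls == 1).sum(axis=0)
    n_bb = (calls == 2).sum(axis=0)
    n_missing = (calls == MISSING).sum(axis=0)
    return n_aa, n_ab, n_bb, n_missing
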