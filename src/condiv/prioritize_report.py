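"""Conservation-priority ranking and pipeline orchestration.

The priority score combines a breed's rank by contribution to total gene
diversity (HT) with its rank by contribution to total allelic diversity
(AT).  Both tables are ranked by descending contribution with competition
ranking ("1, 2, 2, 4") for exact ties; the score is the (optionally
weighted) sum of the two ranks, and a *lower* score means a *higher*
conservation priority.  Equal weights are the default; the two metrics
capture complementary goals (short-term genetic health vs long-term allelic
reservoir), and a weight parameter is exposed for contexts that value one
over the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import between_diversity, ld_ne, partition_contrib, within_diversity
from .panel import GenotypePanel
from .partition_contrib import ContributionTable


@dataclass
class ColumnSummary:
    """Mean / min / max of one metric with breed attribution."""

    metric: str
    mean: float
    min: float
    max: float
    argmin: str
    argmax: str
    n: int

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.min), abs(self.max))
        if not (self.min - tol <= self.mean <= self.max + tol):
            raise ValueError(f"{self.metric}: min <= mean <= max violated")


def summarize_columns(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    label_col: str = "breed_code",
) -> dict[str, ColumnSummary]:
    """Exact column summaries (mean, range, attributed extremes).

    Arithmetic is exact on the stored values; rounding is left to
    presentation.
    """
    if len(table) == 0:
        raise ValueError("empty summary table")
    if metrics is None:
        metrics = [c for c in table.columns if c != label_col and pd.api.types.is_numeric_dtype(table[c])]
    out = {}
    for m in metrics:
        col = table[m].astype(float)
        out[m] = ColumnSummary(
            metric=m,
            mean=float(col.mean()),
            min=float(col.min()),
            max=float(col.max()),
            argmin=str(table[label_col].iloc[int(col.values.argmin())]),
            argmax=str(table[label_col].iloc[int(col.values.argmax())]),
            n=len(col),
        )
    return out


def combined_priority(
    contrib_gene: ContributionTable | pd.DataFrame,
    contrib_allelic: ContributionTable | pd.DataFrame,
    weight_gene: float = 1.0,
    weight_allelic: float = 1.0,
) -> pd.DataFrame:
    """Combine gene- and allelic-diversity contribution ranks into a score.

    Both tables must cover the same breed set.  Returns a frame sorted by
    ascending score (ties broken alphabetically for display only) with
    columns ``breed_code, contrib_gene, contrib_allelic, rank_HT, rank_AT,
    score, final_rank``.
    """
    g = contrib_gene.data if isinstance(contrib_gene, ContributionTable) else contrib_gene
    a = contrib_allelic.data if isinstance(contrib_allelic, ContributionTable) else contrib_allelic
    gs, as_ = set(g["breed_code"]), set(a["breed_code"])
    if gs != as_:
        only_g = sorted(gs - as_)
        only_a = sorted(as_ - gs)
        raise ValueError(
            f"breed sets differ: only in gene table {only_g}; only in allelic table {only_a}"
        )
    merged = pd.merge(
        g[["breed_code", "c_total"]].rename(columns={"c_total": "contrib_gene"}),
        a[["breed_code", "c_total"]].rename(columns={"c_total": "contrib_allelic"}),
        on="breed_code",
    )
    merged["rank_HT"] = (
        merged["contrib_gene"].rank(ascending=False, method="min").astype(int)
    )
    merged["rank_AT"] = (
        merged["contrib_allelic"].rank(ascending=False, method="min").astype(int)
    )
    merged["score"] = weight_gene * merged["rank_HT"] + weight_allelic * merged["rank_AT"]
    if weight_gene == 1.0 and weight_allelic == 1.0:
        merged["score"] = merged["score"].astype(int)
    merged["final_rank"] = merged["score"].rank(method="min").astype(int)
    return merged.sort_values(["score", "breed_code"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(
    panel: GenotypePanel,
    out_dir: str | Path,
    *,
    max_missing_rate: float = 0.10,
    min_maf: float = 0.05,
    autosome_labels: set[str] | None = None,
    rarefaction: str = "min",
    ld: bool = False,
    ld_breeds: list[str] | None = None,
    ld_max_dist_bp: int = 1_000_000,
    ld_n_bins: int = 20,
    ld_max_pairs_per_chrom: int | None = 50_000,
    map_rate_cm_per_mb: float = 1.0,
    seed: int = 0,
) -> dict:
    """Run qc -> diversity -> between -> partition -> (ld) -> prioritise.

    Writes TSV tables, a Newick tree and a machine-readable ``report.json``
    under ``out_dir`` and returns the report dictionary.  All outputs are
    deterministic for a given panel and seed (no timestamps).
    """
    from .genotype_io import apply_qc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "settings": {
            "max_missing_rate": max_missing_rate,
            "min_maf": min_maf,
            "rarefaction": rarefaction,
            "ld": ld,
            "ld_max_dist_bp": ld_max_dist_bp,
            "ld_n_bins": ld_n_bins,
            "ld_max_pairs_per_chrom": ld_max_pairs_per_chrom,
            "map_rate_cm_per_mb": map_rate_cm_per_mb,
            "seed": seed,
        }
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort with the stage named
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # qc
    def _qc():
        filtered, qc = apply_qc(panel, max_missing_rate, min_maf, autosome_labels)
        (out / "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=2, sort_keys=True))
        return filtered, qc

    filtered, qc = stage("qc", _qc)
    report["qc"] = qc.to_dict()

    # within-breed diversity
    def _div():
        table = within_diversity.diversity_summary(filtered)
        footer = summarize_columns(table, ["Ho", "He", "MAF", "FHOM", "fii", "si"])
        _write_tsv(table, out / "diversity.tsv")
        return table, footer

    div_table, footer = stage("diversity", _div)
    report["diversity_summary"] = {
        m: {"mean": s.mean, "min": s.min, "max": s.max, "argmin": s.argmin, "argmax": s.argmax}
        for m, s in footer.items()
    }

    # between-breed
    def _between():
        dm = between_diversity.nei_distance_matrix(filtered)
        dm.to_frame().to_csv(out / "nei_distances.tsv", sep="\t", float_format="%.10g")
        fst = between_diversity.fst_table(filtered)
        _write_tsv(fst, out / "fst.tsv")
        theta = between_diversity.wc_fst_global(filtered)
        newick = between_diversity.neighbor_joining(dm)
        (out / "tree.nwk").write_text(newick + "\n")
        return theta

    report["global_theta"] = stage("between", _between)

    # partitions and contributions
    def _partition():
        gene = partition_contrib.gene_diversity_partition(filtered)
        allelic = partition_contrib.allelic_partition(filtered, rarefaction=rarefaction)
        cg = partition_contrib.loo_contribution(filtered, which="gene")
        ca = partition_contrib.loo_contribution(filtered, which="allelic", rarefaction=rarefaction)
        _write_tsv(cg.data, out / "contributions_gene.tsv")
        _write_tsv(ca.data, out / "contributions_allelic.tsv")
        part = {
            "gene": {"HT": gene.HT, "HS": gene.HS, "DG": gene.DG, "f_bar": gene.f_bar},
            "allelic": {"AT": allelic.AT, "AS": allelic.AS, "DA": allelic.DA,
                        "rarefaction": allelic.rarefaction_g},
        }
        (out / "partition.json").write_text(json.dumps(part, indent=2, sort_keys=True))
        return part, cg, ca

    part, cg, ca = stage("partition", _partition)
    report["partition"] = part

    # priority
    def _priority():
        ranking = combined_priority(cg, ca)
        _write_tsv(ranking, out / "priority.tsv")
        return ranking

    ranking = stage("prioritize", _priority)
    report["priority"] = ranking.to_dict(orient="records")

    # LD / Ne (optional)
    if ld:
        def _ld():
            edges = np.linspace(0, ld_max_dist_bp, ld_n_bins + 1)
            results = {}
            for breed in ld_breeds or filtered.breed_codes:
                pairs = ld_ne.pairwise_r2(
                    filtered,
                    breed,
                    max_dist_bp=ld_max_dist_bp,
                    max_pairs_per_chrom=ld_max_pairs_per_chrom,
                    seed=seed,
                )
                if pairs[0].size == 0:
                    continue
                curve = ld_ne.ld_decay_curve(pairs, edges, breed_code=breed)
                n_breed = len(filtered.sample_indices(breed))
                traj = ld_ne.ne_from_ld(curve, map_rate_cm_per_mb, mean_n=n_breed)
                _write_tsv(curve.to_frame(), out / f"ld_curve_{breed}.tsv")
                _write_tsv(traj.to_frame(), out / f"ne_{breed}.tsv")
                results[breed] = {
                    "first_bin_r2": curve.bins[0][3],
                    "n_pairs": int(sum(b[4] for b in curve.bins)),
                }
            return results

        report["ld"] = stage("ld", _ld)
    else:
        report["ld"] = "skipped"

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
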