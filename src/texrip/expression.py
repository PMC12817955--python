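"""Expression normalization, differential-expression stand-in, and the
asRNA/mRNA co-regulation analyses.

An antisense RNA (asRNA) overlapping a gene on the opposite strand forms a
pair with that gene; the Pearson correlation coefficient (PCC) of their log2
fold-change vectors across experimental contrasts classifies the pair as
positively correlated (PCC >= 0.5), negatively correlated (PCC <= -0.5) or
uncorrelated.  Correlated pairs feed a direction-agreement analysis per
heat-stress timepoint, a protein-level integration (up/down/unchanged joint
categories), and bound-vs-unbound trajectory summaries for RIP-seq target
sets.

Differential expression follows the usual conventions: |log2FC| >= 1 with
p < 0.05.  The built-in DE stand-in uses median-of-ratios size factors, a
log2 fold change of mean normalized counts with a 0.5 pseudocount, and a
Welch test on log2 normalized counts with BH adjustment; externally produced
DE tables (e.g. DESeq2 output) are accepted as a drop-in via
``texrip.io.read_fold_change_table``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomeAnnotation

PCC_THRESHOLD = 0.5
DE_LFC_THRESHOLD = 1.0
DE_P_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Normalization and the DE stand-in
# ---------------------------------------------------------------------------

def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: TPM_i = 1e6 * (c_i/l_i) / sum_j (c_j/l_j).

    All-zero counts return an all-zero vector rather than dividing by zero.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


def log_tpm(counts, lengths) -> np.ndarray:
    return np.log2(tpm(counts, lengths) + 1.0)


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x samples matrix).

    Each sample's factor is the median, over features with a positive
    geometric mean, of count / geometric-mean-count.
    """
    log_counts = np.log(count_matrix.where(count_matrix > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean) & count_matrix.notna().all(axis=1)
    if not usable.any():
        raise ValueError("no feature has positive counts in every sample")
    ratios = np.log(count_matrix.loc[usable]).sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def de_stand_in(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    p_threshold: float = DE_P_THRESHOLD,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Simple two-group differential expression (group b vs group a).

    Returns a table with feature_id, log2fc, pvalue, padj and a significance
    flag (|log2FC| >= lfc_threshold and p < p_threshold).  Requires at least
    two replicates per group.
    """
    if not counts_a.index.equals(counts_b.index):
        missing = set(counts_a.index) ^ set(counts_b.index)
        raise ValueError(f"feature sets differ between groups: {sorted(missing)[:5]}")
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("at least 2 replicates per group are required")
    combined = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(combined)
    norm = combined / sf
    norm_a = norm.iloc[:, : counts_a.shape[1]]
    norm_b = norm.iloc[:, counts_a.shape[1]:]
    lfc = np.log2(
        (norm_b.mean(axis=1) + pseudocount) / (norm_a.mean(axis=1) + pseudocount)
    )
    log_a = np.log2(norm_a + pseudocount)
    log_b = np.log2(norm_b + pseudocount)
    t = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    pvalue = pd.Series(t.pvalue, index=combined.index).fillna(1.0)
    _, padj, _, _ = multipletests(pvalue.values, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature_id": combined.index,
            "log2fc": lfc.values,
            "pvalue": pvalue.values,
            "padj": padj,
            "significant": (np.abs(lfc.values) >= lfc_threshold)
            & (pvalue.values < p_threshold),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# asRNA/mRNA pairs and correlation classes
# ---------------------------------------------------------------------------

@dataclass
class PairRecord:
    """One (gene, antisense RNA) pair with its expression correlation."""

    mrna_id: str
    asrna_id: str
    overlap_nt: int
    pcc: float | None = None
    n_contrasts_used: int = 0
    corr_class: str = "uncorrelated"


def build_pairs(annotation: GenomeAnnotation) -> list[PairRecord]:
    """One PairRecord per (gene, asRNA) opposite-strand overlap of >= 1 nt."""
    genes = annotation.of_type("gene")
    asrnas = annotation.of_type("asRNA")
    pairs = []
    for asrna in asrnas:
        for gene in genes:
            if gene.strand == asrna.strand:
                continue
            ov = gene.overlap(asrna.start, asrna.end)
            if ov >= 1:
                pairs.append(PairRecord(gene.id, asrna.id, ov))
    return pairs


def classify_pcc(pcc: float | None, threshold: float = PCC_THRESHOLD) -> str:
    if pcc is None or not np.isfinite(pcc):
        return "uncorrelated"
    if pcc >= threshold:
        return "positive"
    if pcc <= -threshold:
        return "negative"
    return "uncorrelated"


def pair_pcc(
    pair: PairRecord,
    lfc_mrna: pd.Series,
    lfc_asrna: pd.Series,
    threshold: float = PCC_THRESHOLD,
) -> PairRecord:
    """Pearson correlation of the pair's log2FC vectors across contrasts.

    Only contrasts finite in both vectors count; with fewer than 3 shared
    contrasts, or a zero-variance vector, the PCC is missing (not 0) and the
    pair is classed uncorrelated.
    """
    shared = lfc_mrna.index.intersection(lfc_asrna.index)
    x = lfc_mrna[shared].astype(float)
    y = lfc_asrna[shared].astype(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok].values, y[ok].values
    pair.n_contrasts_used = len(x)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        pair.pcc = None
        pair.corr_class = "uncorrelated"
        return pair
    pair.pcc = float(np.corrcoef(x, y)[0, 1])
    pair.corr_class = classify_pcc(pair.pcc, threshold)
    return pair


def correlate_pairs(
    pairs: Iterable[PairRecord],
    lfc_mrna: pd.DataFrame,
    lfc_asrna: pd.DataFrame,
    threshold: float = PCC_THRESHOLD,
) -> list[PairRecord]:
    """Run ``pair_pcc`` over wide (feature x contrast) log2FC matrices."""
    out = []
    for pair in pairs:
        if pair.mrna_id in lfc_mrna.index and pair.asrna_id in lfc_asrna.index:
            pair = pair_pcc(
                pair, lfc_mrna.loc[pair.mrna_id], lfc_asrna.loc[pair.asrna_id], threshold
            )
        out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Direction agreement, protein integration, trajectories
# ---------------------------------------------------------------------------

@dataclass
class DirectionSummary:
    timepoint: str
    n_pairs: int
    pct_same: float
    pct_opposite: float


def direction_agreement(
    pairs: Iterable[PairRecord],
    lfc_mrna_t: pd.Series,
    lfc_asrna_t: pd.Series,
    timepoint: str = "",
    min_abs_pcc: float = PCC_THRESHOLD,
) -> DirectionSummary:
    """Fraction of correlated pairs moving in the same vs opposite direction.

    Pairs pass the filter when |PCC| >= min_abs_pcc; a pair with either
    log2FC equal to zero (sign undefined) is excluded from the denominator.
    """
    same = opposite = 0
    for pair in pairs:
        if pair.pcc is None or abs(pair.pcc) < min_abs_pcc:
            continue
        if pair.mrna_id not in lfc_mrna_t.index or pair.asrna_id not in lfc_asrna_t.index:
            continue
        a = float(lfc_mrna_t[pair.mrna_id])
        b = float(lfc_asrna_t[pair.asrna_id])
        if not (np.isfinite(a) and np.isfinite(b)) or a == 0 or b == 0:
            continue
        if a * b > 0:
            same += 1
        else:
            opposite += 1
    n = same + opposite
    if n == 0:
        raise ValueError("no pairs pass the correlation/direction filters")
    # compute the larger share directly and the smaller as its complement so
    # the two percentages sum to exactly 100 in floating point
    pct_same = 100.0 * same / n
    if pct_same >= 50.0:
        pct_opposite = 100.0 - pct_same
    else:
        pct_opposite = 100.0 * opposite / n
        pct_same = 100.0 - pct_opposite
    return DirectionSummary(
        timepoint=timepoint, n_pairs=n, pct_same=pct_same, pct_opposite=pct_opposite
    )


def _classify_change(
    lfc: float, pvalue: float, lfc_threshold: float, p_threshold: float
) -> str:
    if np.isfinite(lfc) and np.isfinite(pvalue) and pvalue < p_threshold:
        if lfc >= lfc_threshold:
            return "up"
        if lfc <= -lfc_threshold:
            return "down"
    return "unchanged"


def protein_integration(
    pairs: Iterable[PairRecord],
    table_asrna: pd.DataFrame,
    table_protein: pd.DataFrame,
    table_mrna: pd.DataFrame,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    p_threshold: float = DE_P_THRESHOLD,
) -> pd.DataFrame:
    """Joint up/down/unchanged categories for asRNA, mRNA and protein.

    Each input table is indexed by feature id with columns log2fc and pvalue.
    Protein rows are looked up under the pair's gene id; pairs without
    protein data are excluded (their count is reported in the attrs of the
    returned frame).  Percentage columns are over the included pairs.
    """
    rows = []
    n_missing = 0
    for pair in pairs:
        if (
            pair.asrna_id not in table_asrna.index
            or pair.mrna_id not in table_mrna.index
        ):
            n_missing += 1
            continue
        if pair.mrna_id not in table_protein.index:
            n_missing += 1
            continue
        entry = {"mrna_id": pair.mrna_id, "asrna_id": pair.asrna_id}
        for label, table, key in (
            ("asrna", table_asrna, pair.asrna_id),
            ("mrna", table_mrna, pair.mrna_id),
            ("protein", table_protein, pair.mrna_id),
        ):
            rec = table.loc[key]
            entry[f"{label}_log2fc"] = float(rec["log2fc"])
            entry[f"{label}_class"] = _classify_change(
                float(rec["log2fc"]), float(rec["pvalue"]), lfc_threshold, p_threshold
            )
        entry["category"] = (
            f"asRNA-{entry['asrna_class']}/protein-{entry['protein_class']}"
        )
        rows.append(entry)
    df = pd.DataFrame(rows)
    df.attrs["n_excluded_missing"] = n_missing
    return df


def change_percentages(integration: pd.DataFrame, molecule: str) -> pd.Series:
    """Percentages of up/down/unchanged for one molecule type; sums to 100."""
    counts = integration[f"{molecule}_class"].value_counts()
    pct = 100.0 * counts / counts.sum()
    return pct.reindex(["up", "down", "unchanged"], fill_value=0.0)


def smap_group_trajectories(
    targets: Mapping[str, set[str]],
    lfc_tables: Mapping[str, pd.DataFrame],
    universe: set[str],
    sig_tiers: tuple[float, float] = (0.05, 0.005),
) -> pd.DataFrame:
    """Mean log2FC trajectories of bound vs unbound transcripts per timepoint.

    ``targets`` maps protein name to its target-id set (e.g. smap1, smap2).
    Groups are <protein>-only for each protein, "both" (intersection over all
    proteins) and "unbound" (universe minus any target).  Per timepoint each
    bound group is compared to the unbound group with a two-sided
    Mann-Whitney U test; BH adjustment is applied within the timepoint, and
    significance tiers follow padj < 0.05 (*) and < 0.005 (***).
    """
    names = sorted(targets)
    all_bound: set[str] = set().union(*targets.values()) if targets else set()
    groups: dict[str, set[str]] = {}
    if len(names) >= 2:
        both = set.intersection(*(targets[n] for n in names))
        for n in names:
            groups[f"{n}-only"] = targets[n] - (all_bound - targets[n])
        groups["both"] = both
    else:
        for n in names:
            groups[f"{n}-only"] = set(targets[n])
    groups["unbound"] = universe - all_bound

    rows = []
    for timepoint, table in lfc_tables.items():
        lfc = table["log2fc"] if "log2fc" in table else table
        unbound_vals = lfc.reindex(sorted(groups["unbound"])).dropna().values
        tp_rows = []
        pvals = []
        for group_name, members in groups.items():
            vals = lfc.reindex(sorted(members)).dropna().values
            if len(vals) == 0:
                continue
            row = {
                "timepoint": timepoint,
                "group": group_name,
                "n": len(vals),
                "mean_log2fc": float(np.mean(vals)),
                "sem": float(stats.sem(vals)) if len(vals) > 1 else np.nan,
                "pvalue": np.nan,
            }
            if group_name != "unbound" and len(unbound_vals) > 0 and len(vals) > 0:
                _, p = stats.mannwhitneyu(vals, unbound_vals, alternative="two-sided")
                row["pvalue"] = float(p)
                pvals.append(len(tp_rows))
            tp_rows.append(row)
        if pvals:
            raw = [tp_rows[i]["pvalue"] for i in pvals]
            _, padj, _, _ = multipletests(raw, method="fdr_bh")
            for i, q in zip(pvals, padj):
                tp_rows[i]["padj"] = float(q)
                tp_rows[i]["sig_tier"] = (
                    "***" if q < sig_tiers[1] else "*" if q < sig_tiers[0] else "ns"
                )
        rows.extend(tp_rows)
    return pd.DataFrame(rows)
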