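"""MPRA barcode-count processing: from RNA/DNA read counts to log2 activity.

The processing chain is fixed:

1. drop barcodes with fewer than 50 reads in the plasmid (DNA) pool,
2. normalize each sample (RNA or DNA, per replicate) to reads per million,
3. per-barcode RNA/DNA RPM ratio,
4. mean ratio over a CRE's barcodes (per replicate),
5. divide by the basal promoter's mean ratio (per replicate),
6. mean over replicates, then log2.

No pseudocount is added: a barcode with zero RNA reads contributes a ratio
of zero.  Count tables are taken as given — barcode demultiplexing and
quality filtering are upstream concerns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "filter_barcodes",
    "rpm_normalize",
    "cre_activity",
    "replicate_correlation",
    "COUNT_COLUMNS",
]

COUNT_COLUMNS = ["barcode", "cre_id", "replicate", "rna_reads", "dna_reads"]


def _check_counts(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("empty count table")
    if (records["rna_reads"] < 0).any() or (records["dna_reads"] < 0).any():
        raise ValueError("negative read counts")
    return records


def filter_barcodes(records: pd.DataFrame, min_plasmid_reads: int = 50) -> pd.DataFrame:
    """Remove barcodes with fewer than ``min_plasmid_reads`` DNA reads.

    The boundary is kept: "fewer than 50" removes 49 and retains 50.
    Attaches the retained read fraction as ``.attrs["retained_read_fraction"]``.
    """
    _check_counts(records)
    keep = records["dna_reads"] >= min_plasmid_reads
    out = records.loc[keep].copy()
    total = records[["rna_reads", "dna_reads"]].to_numpy().sum()
    retained = out[["rna_reads", "dna_reads"]].to_numpy().sum()
    out.attrs["retained_read_fraction"] = float(retained / total) if total else 0.0
    if len(out) == 0:
        warnings.warn("all barcodes fell below the plasmid-read threshold", stacklevel=2)
    return out


def rpm_normalize(counts) -> np.ndarray:
    """Reads-per-million within one sample: rpm_i = 1e6 * reads_i / sum(reads)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total sample reads must be positive")
    return 1e6 * counts / total


def cre_activity(records: pd.DataFrame, basal_id: str) -> pd.DataFrame:
    """Per-CRE activities, basal-normalized, averaged over replicates, log2.

    Parameters
    ----------
    records : DataFrame
        Filtered count table with columns ``barcode, cre_id, replicate,
        rna_reads, dna_reads``.  RPM normalization happens here, per
        replicate sample, so pass the post-filter table directly.
    basal_id : str
        ``cre_id`` of the basal promoter construct; its activity defines
        1.0 (0 on the log2 scale) within each replicate.

    Returns
    -------
    DataFrame indexed by ``cre_id`` with one ``activity_rep<r>`` column per
    replicate, plus ``mean_activity`` and ``log2_activity``.
    """
    _check_counts(records)
    if basal_id not in set(records["cre_id"]):
        raise ValueError(f"basal CRE {basal_id!r} absent from the count table")

    per_rep = {}
    for rep, sub in records.groupby("replicate"):
        sub = sub.copy()
        sub["rna_rpm"] = rpm_normalize(sub["rna_reads"])
        sub["dna_rpm"] = rpm_normalize(sub["dna_reads"])
        zero_dna = sub["dna_rpm"] == 0
        if zero_dna.any():
            warnings.warn(
                f"replicate {rep}: {int(zero_dna.sum())} barcode(s) with zero DNA rpm excluded",
                stacklevel=2,
            )
            sub = sub.loc[~zero_dna]
        sub["ratio"] = sub["rna_rpm"] / sub["dna_rpm"]
        mean_ratio = sub.groupby("cre_id")["ratio"].mean()
        if basal_id not in mean_ratio.index or mean_ratio[basal_id] <= 0:
            raise ValueError(f"replicate {rep}: basal CRE has no usable barcodes")
        per_rep[rep] = mean_ratio / mean_ratio[basal_id]

    table = pd.DataFrame({f"activity_rep{r}": s for r, s in sorted(per_rep.items())})
    table.index.name = "cre_id"
    table["mean_activity"] = table.mean(axis=1)
    with np.errstate(divide="ignore"):
        table["log2_activity"] = np.log2(table["mean_activity"])
    return table


def replicate_correlation(activity: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pairwise R^2 of per-replicate log activities, and their mean.

    ``activity`` is the output of :func:`cre_activity` (or any frame with
    ``activity_rep*`` columns).  Log activities of each replicate pair are
    correlated over their shared, strictly positive CREs.
    """
    rep_cols = [c for c in activity.columns if c.startswith("activity_rep")]
    if len(rep_cols) < 2:
        raise ValueError("need >= 2 replicates")
    logs = np.log2(activity[rep_cols].where(activity[rep_cols] > 0))
    n = len(rep_cols)
    r2 = pd.DataFrame(np.ones((n, n)), index=rep_cols, columns=rep_cols)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = logs[[rep_cols[i], rep_cols[j]]].dropna()
            if len(pair) < 2:
                raise ValueError("fewer than 2 shared CREs between replicates")
            r = np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1]
            r2.iloc[i, j] = r2.iloc[j, i] = r**2
            vals.append(r**2)
    return r2, float(np.mean(vals))
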