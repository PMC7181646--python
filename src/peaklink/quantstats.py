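"""Table-level expression and qPCR statistics.

FPKM normalization, Benjamini-Hochberg FDR adjustment, differential
expression thresholding, and ChIP-qPCR quantification via an input-DNA
standard curve expressed as fold over the IgG control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj", "base_mean"]


def fpkm(count: int, gene_length: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads.

    fpkm = count * 1e9 / (gene_length * total_mapped); invariant to a
    common rescaling of count and total_mapped.
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (gene_length * total_mapped)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * n / j over the ascending ranking,
    capped at 1; preserves the ordering of the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(n)
    out[order] = adj
    return out


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV with columns
    gene_id, log2fc, pvalue, padj, base_mean."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns: {', '.join(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    both = df["padj"].notna() & df["pvalue"].notna()
    if (df.loc[both, "padj"] < df.loc[both, "pvalue"] - 1e-12).any():
        raise ValueError(f"{path}: padj smaller than pvalue")
    return df


def de_filter(
    table: pd.DataFrame,
    mode: str = "replicates",
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    direction: str = "all",
) -> set[str]:
    """Differentially expressed gene ids under the study's thresholds.

    mode="replicates": padj < alpha (strict).  mode="no_replicates":
    padj < alpha and |log2fc| >= min_abs_log2fc.  ``direction`` can
    restrict to "up" (log2fc > 0) or "down" (log2fc < 0).
    """
    if mode not in ("replicates", "no_replicates"):
        raise ValueError(f"unknown mode {mode!r}")
    if direction not in ("all", "up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    if "padj" not in table.columns:
        raise ValueError("DE table lacks the padj column")
    keep = table["padj"].notna() & (table["padj"] < alpha)
    if mode == "no_replicates":
        keep &= table["log2fc"].abs() >= min_abs_log2fc
    if direction == "up":
        keep &= table["log2fc"] > 0
    elif direction == "down":
        keep &= table["log2fc"] < 0
    return set(table.loc[keep, "gene_id"])


@dataclass
class QpcrCurve:
    """Least-squares standard curve ct = slope * log10(amount) + intercept.

    A valid dilution series has a negative slope (about -3.32 Ct per
    10-fold dilution at 100% amplification efficiency).
    """

    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r2: float

    def quantity(self, ct: float) -> float:
        """Amount (same units as the dilution series) for an observed Ct."""
        if self.slope == 0:
            raise ValueError("degenerate standard curve: slope is 0")
        return 10 ** ((ct - self.intercept) / self.slope)


def qpcr_fit_curve(points: Sequence[tuple[float, float]]) -> QpcrCurve:
    """Fit a qPCR standard curve to (log10_amount, ct) dilution points."""
    if len(points) < 2:
        raise ValueError("standard curve needs >= 2 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("standard curve needs >= 2 distinct dilution amounts")
    res = sps.linregress(x, y)
    return QpcrCurve(
        points=[(float(a), float(b)) for a, b in points],
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def chip_fold_enrichment(
    sample_ct: float,
    input_ct: float,
    igg_ct: float,
    curve: QpcrCurve,
    input_fraction: float = 0.01,
) -> float:
    """ChIP-qPCR fold enrichment over the IgG control.

    Quantities come off the standard curve; each IP is normalized to
    input DNA (corrected for the input fraction assayed) and the sample
    percent-input is ratioed against the IgG percent-input.  The input
    fraction cancels algebraically but is kept for percent-input
    reporting parity.
    """
    if input_fraction <= 0:
        raise ValueError("input_fraction must be positive")
    q_in = curve.quantity(input_ct) / input_fraction
    pct_sample = curve.quantity(sample_ct) / q_in
    pct_igg = curve.quantity(igg_ct) / q_in
    return pct_sample / pct_igg
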