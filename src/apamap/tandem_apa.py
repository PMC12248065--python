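"""Classification of DaPars-style dPDUI tables and per-RBP summaries.

PDUI (Percentage of Distal polyA-site Usage Index) is the fraction of a
terminal exon's expression using the distal PAS; dPDUI = PDUI_control -
PDUI_knockdown.  With this sign convention, an RBP that normally promotes
the distal site ("RBP lengthens the 3'UTR") shows dPDUI > 0 on knockdown.
A terminal exon is *changing* when |dPDUI| >= 20% with an adjusted p below
0.05 and *non-changing* when |dPDUI| < 5% with an adjusted p above 0.05;
everything else (including rows lacking a p-value) is *other*.  "FDR" and
"adjusted p-value" are treated as the same provided column; no
multiple-testing procedure is re-run here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CLASSES = ("rbp_lengthens", "rbp_shortens", "non_changing", "other")

# tolerant readers for native DaPars-flavoured column names
_COLUMN_ALIASES = {
    "exon_id": ("exon_id", "Event_id", "event_id", "Loci"),
    "gene_id": ("gene_id", "Gene", "gene"),
    "PDUI_ctrl": ("PDUI_ctrl", "PDUI_control", "Group_A_Mean_PDUI", "A_PDUI"),
    "PDUI_kd": ("PDUI_kd", "PDUI_knockdown", "Group_B_Mean_PDUI", "B_PDUI"),
    "p_adj": ("p_adj", "adjusted.P_val", "adjusted_p", "FDR", "fdr", "padj"),
}


def normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Map DaPars-flavoured column names onto the canonical ones."""
    renames = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in table.columns:
                renames[a] = canon
                break
    df = table.rename(columns=renames).copy()
    missing = {"exon_id", "PDUI_ctrl", "PDUI_kd"} - set(df.columns)
    if missing:
        raise ValueError(f"dPDUI table lacks required columns: {sorted(missing)}")
    if "gene_id" not in df.columns:
        df["gene_id"] = df["exon_id"]
    return df


def classify_calls(table: pd.DataFrame, delta_thresh: float = 0.20,
                   sig_alpha: float = 0.05, null_delta: float = 0.05,
                   ) -> pd.DataFrame:
    """Classify each terminal exon by (|dPDUI|, adjusted p) thresholds.

    Returns the normalized table with ``dPDUI`` and ``class`` columns.  Rows
    with a missing adjusted p are classed ``other`` with a warning.
    """
    df = normalize_table(table)
    df["dPDUI"] = df["PDUI_ctrl"] - df["PDUI_kd"]
    if "p_adj" not in df.columns:
        warnings.warn("table has no adjusted-p column; all rows classed 'other'")
        df["p_adj"] = np.nan
    n_missing = int(df["p_adj"].isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} rows lack an adjusted p; classed 'other'")
    d = df["dPDUI"]
    p = df["p_adj"]
    cls = np.full(len(df), "other", dtype=object)
    changing = (d.abs() >= delta_thresh) & (p < sig_alpha)
    cls[changing & (d > 0)] = "rbp_lengthens"
    cls[changing & (d < 0)] = "rbp_shortens"
    cls[(d.abs() < null_delta) & (p > sig_alpha)] = "non_changing"
    cls[p.isna()] = "other"
    df["class"] = cls
    return df


def summarize_rbp(calls: pd.DataFrame, rbp_id: str = "",
                  cell_context: str = "") -> dict:
    """Per-RBP summary: unique changing genes and lengthening/shortening split.

    A gene with several changing terminal exons counts once; fractions are
    over changing exons and sum to 1 when any exist.
    """
    changing = calls[calls["class"].isin(("rbp_lengthens", "rbp_shortens"))]
    n_exons = len(changing)
    n_len = int((changing["class"] == "rbp_lengthens").sum())
    return {
        "rbp_id": rbp_id,
        "cell_context": cell_context,
        "n_changing_exons": n_exons,
        "n_unique_genes": int(changing["gene_id"].nunique()),
        "fraction_lengthening": n_len / n_exons if n_exons else float("nan"),
        "fraction_shortening": (n_exons - n_len) / n_exons if n_exons else float("nan"),
    }


def estimate_pdui(coverage: np.ndarray, proximal_pas: int, distal_pas: int,
                  ) -> float:
    """Simplified two-PAS PDUI from per-base coverage over a terminal exon.

    The coverage vector is in transcript orientation (index 0 = exon 5' end);
    ``proximal_pas`` must be 5' of ``distal_pas``.  PDUI is the mean coverage
    of the extended region (proximal, distal] over the mean coverage of the
    common region 5' of the proximal PAS, clamped to [0, 1].  This is a
    uniform-coverage plumbing estimator for synthetic tests, not a de-novo
    PAS-inference algorithm.
    """
    cov = np.asarray(coverage, dtype=float)
    if not 0 < proximal_pas < distal_pas <= cov.size:
        raise ValueError("require 0 < proximal_pas < distal_pas <= len(coverage)")
    common = cov[:proximal_pas].mean()
    extended = cov[proximal_pas:distal_pas].mean()
    if common <= 0:
        return 0.0
    return float(np.clip(extended / common, 0.0, 1.0))
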