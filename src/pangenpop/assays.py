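"""Closed-form phenotype and expression calculators.

Relative electrolyte conductivity (REC) as a cold-injury proxy, MDA
(malondialdehyde) content from the absorbance differential of the
thiobarbituric-acid assay, and qPCR relative expression by the
2^-ddCt method.  Batch helpers average over biological replicates on
the raw measurements before transformation.
"""

from __future__ import annotations

import pandas as pd


def rec_percent(r1: float, r2: float) -> float:
    """Relative electrolyte conductivity R1/R2 x 100 (%).

    R1: conductivity before boiling; R2: after boiling (total
    electrolyte release).  R2 must be positive.
    """
    if r2 <= 0:
        raise ValueError("R2 (post-boil conductivity) must be positive")
    if r1 < 0:
        raise ValueError("R1 must be non-negative")
    return r1 / r2 * 100.0


def mda_content(a532: float, a600: float, weight_g: float) -> float:
    """MDA content, nmol per g fresh weight: 25.58 x (dA + 0.0076) / W.

    dA = A532 - A600 corrects the 532 nm reading for non-specific
    turbidity at 600 nm; W is fresh tissue weight in grams.
    """
    if weight_g <= 0:
        raise ValueError("fresh weight must be positive")
    return 25.58 * ((a532 - a600) + 0.0076) / weight_g


def relative_expression(ct_target_treat: float, ct_ref_treat: float,
                        ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Fold change by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_treatment - (Ct_target - Ct_ref)_control.
    """
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def summarize_replicates(df: pd.DataFrame, value: str,
                         by: list[str]) -> pd.DataFrame:
    """Mean and sd of a raw measurement over biological replicates."""
    g = df.groupby(by)[value]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": f"{value}_mean", "std": f"{value}_sd",
                               "count": "n_replicates"})


def rec_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply rec_percent row-wise to a frame with r1, r2 columns."""
    out = df.copy()
    out["rec_percent"] = [rec_percent(r1, r2) for r1, r2 in zip(df["r1"], df["r2"])]
    return out


def mda_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply mda_content row-wise to a frame with a532, a600, weight_g."""
    out = df.copy()
    out["mda_nmol_per_g"] = [mda_content(a, b, w) for a, b, w
                             in zip(df["a532"], df["a600"], df["weight_g"])]
    return out
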