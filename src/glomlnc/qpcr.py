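"""Relative quantification of qPCR data by the 2^-ddCt method.

Technical triplicates are averaged per sample first; the biological
animal is the unit of replication.  Expression is normalized to a
reference gene (cyclophilin B by default), fold change is 2^-ddCt, and
group differences are gated by one-way ANOVA on per-sample dCt at the 5%
level.  Undetected wells are encoded explicitly (NaN Ct), never as an
arbitrary high cycle number.

For cell-panel data, the Ct ratio (target Ct / reference Ct) is banded:
a low ratio (< 1.0) indicates high expression, a high ratio (> 1.8) low
expression, values between are intermediate, and an undetected target is
reported as no expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE = "Ppib"  # cyclophilin B

CT_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class DdctResult:
    gene: str
    stratum: str | None
    ddct: float
    fold_change: float
    sd_fold: float
    p_anova: float
    significant: bool
    n_case: int
    n_control: int
    undetected: bool = False


def _mean_ct_per_sample(ct: pd.DataFrame, gene: str) -> pd.Series:
    """Average technical replicates; all-undetected samples give NaN."""
    sub = ct[ct["gene"] == gene]
    return sub.groupby("sample")["ct"].mean()


def ddct(
    ct: pd.DataFrame,
    gene: str,
    case_group: str,
    control_group: str,
    reference_gene: str = DEFAULT_REFERENCE,
    stratum: str | None = None,
) -> DdctResult:
    """2^-ddCt fold change of ``gene`` in case vs control animals.

    dCt_sample = Ct_gene - Ct_reference per animal; ddCt is the case-mean
    minus control-mean dCt.  The fold-change dispersion is the SD of
    per-animal fold changes 2^-(dCt - control mean dCt).  p comes from
    one-way ANOVA on per-animal dCt (for two groups this equals the
    pooled t-test, F = t^2).
    """
    required = set(CT_COLUMNS) - set(ct.columns)
    if required:
        raise QpcrError(f"Ct table missing columns {sorted(required)}")
    if stratum is not None:
        if "stratum" not in ct.columns:
            raise QpcrError("Ct table has no stratum column")
        ct = ct[ct["stratum"] == stratum]
        if ct.empty:
            raise QpcrError(f"stratum {stratum!r} absent from Ct table")

    gene_ct = _mean_ct_per_sample(ct, gene)
    ref_ct = _mean_ct_per_sample(ct, reference_gene)
    if ref_ct.empty:
        raise QpcrError(f"reference gene {reference_gene!r} absent from Ct table")
    groups = ct[["sample", "group"]].drop_duplicates().set_index("sample")["group"]
    missing_ref = set(gene_ct.index) - set(ref_ct.dropna().index)
    if missing_ref:
        raise QpcrError(
            f"reference gene undetected/missing for samples {sorted(missing_ref)[:5]}"
        )
    dct = (gene_ct - ref_ct.loc[gene_ct.index]).dropna()
    case = dct[groups.loc[dct.index] == case_group]
    ctrl = dct[groups.loc[dct.index] == control_group]
    if gene_ct.dropna().empty:
        return DdctResult(
            gene=gene, stratum=stratum, ddct=float("nan"),
            fold_change=float("nan"), sd_fold=float("nan"),
            p_anova=float("nan"), significant=False,
            n_case=0, n_control=0, undetected=True,
        )
    if len(case) < 2 or len(ctrl) < 2:
        raise QpcrError(
            f"need >=2 animals per group for {gene}: "
            f"case={len(case)}, control={len(ctrl)}"
        )
    ddct_val = float(case.mean() - ctrl.mean())
    fold = float(2.0 ** (-ddct_val))
    # per-animal fold changes of the case group, relative to control mean
    per_animal = 2.0 ** (-(case - ctrl.mean()))
    sd_fold = float(per_animal.std(ddof=1))
    if np.allclose(case.to_numpy(), case.to_numpy()[0]) and np.allclose(
        ctrl.to_numpy(), ctrl.to_numpy()[0]
    ):
        p = 1.0 if np.isclose(ddct_val, 0.0) else 0.0
    else:
        p = float(stats.f_oneway(case.to_numpy(), ctrl.to_numpy()).pvalue)
    return DdctResult(
        gene=gene,
        stratum=stratum,
        ddct=ddct_val,
        fold_change=fold,
        sd_fold=sd_fold,
        p_anova=p,
        significant=bool(p < 0.05),
        n_case=len(case),
        n_control=len(ctrl),
    )


def ct_ratio_band(
    ct: pd.DataFrame,
    gene: str,
    cell_label: str,
    reference_gene: str = DEFAULT_REFERENCE,
    label_column: str = "sample",
    low_ratio: float = 1.0,
    high_ratio: float = 1.8,
) -> tuple[float, str]:
    """Ct ratio (target / reference) and its expression band for one sample.

    Bands: ratio < 1.0 -> high_expression; ratio > 1.8 -> low_expression;
    otherwise intermediate; undetected target -> no_expression.
    """
    sub = ct[ct[label_column] == cell_label]
    if sub.empty:
        raise QpcrError(f"no Ct rows for {label_column}={cell_label!r}")
    gene_ct = sub.loc[sub["gene"] == gene, "ct"].mean()
    ref_ct = sub.loc[sub["gene"] == reference_gene, "ct"].mean()
    if pd.isna(ref_ct):
        raise QpcrError(f"reference gene undetected in {cell_label!r}")
    if pd.isna(gene_ct):
        return float("nan"), "no_expression"
    ratio = float(gene_ct / ref_ct)
    if ratio < low_ratio:
        return ratio, "high_expression"
    if ratio > high_ratio:
        return ratio, "low_expression"
    return ratio, "intermediate"


def ddct_table(
    ct: pd.DataFrame,
    genes: list[str],
    case_group: str,
    control_group: str,
    reference_gene: str = DEFAULT_REFERENCE,
    stratum: str | None = None,
) -> pd.DataFrame:
    """ddct over a gene panel, as a frame."""
    rows = [
        vars(
            ddct(
                ct, g, case_group, control_group,
                reference_gene=reference_gene, stratum=stratum,
            )
        )
        for g in genes
    ]
    return pd.DataFrame(rows)
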