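"""Cross-study harmonization and the SAM permutation statistic.

The SAM (significance analysis of microarrays) two-class statistic is

    d_i = (mean_case - mean_control) / (s_i + s0)

where s_i is the pooled standard error of the difference and s0 a fudge
factor chosen (Tusher-style) over a percentile grid of s_i to minimize
the coefficient of variation of the median absolute d across windows of
s_i.  Feature-wise q-values follow the original SAM FDR: for a cut at
|d_i|, the expected false calls are the median across label permutations
of the number of permuted |d| at or above the cut, divided by the
observed call count; q is then monotonized to be non-increasing in |d|
and clipped to [0, 1].

Harmonization joins per-study DE tables on a stable gene ID and reports
per-feature direction agreement among the studies where the feature is
significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class CrossDatasetError(ValueError):
    pass


def _d_statistic(
    x: np.ndarray, case_mask: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """SAM d and its denominator scatter s for one labelling."""
    x1 = x[:, case_mask]
    x2 = x[:, ~case_mask]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    pooled = ss / (n1 + n2 - 2)
    s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return (m1 - m2) / np.maximum(s + s0, np.finfo(float).tiny), s


def tusher_s0(d_num: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor minimizing the CV of window-wise MAD of d over an s0 grid.

    ``d_num`` is the numerator (mean difference), ``s`` the per-feature
    scatter.  Candidate s0 values are the percentiles 0, 5, ..., 100 of s;
    windows are the s-quantile slices at 1% steps.
    """
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    num_sorted = d_num[order]
    n = s.size
    edges = np.linspace(0, n, 101).astype(int)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d = num_sorted / (s_sorted + s0)
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                w = d[lo:hi]
                mads.append(np.median(np.abs(w - np.median(w))))
        mads = np.asarray(mads) / 0.64
        mean = mads.mean()
        cv = mads.std(ddof=1) / mean if mean > 0 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_masks(
    n_samples: int, case_mask: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Label permutations as boolean masks; exhaustive when few enough."""
    from itertools import combinations as _comb
    from math import comb

    n_case = int(case_mask.sum())
    total = comb(n_samples, n_case)
    if total <= n_perm:
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, idx in enumerate(_comb(range(n_samples), n_case)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    for i in range(n_perm):
        idx = rng.choice(n_samples, size=n_case, replace=False)
        masks[i, idx] = True
    return masks


def sam_test(
    matrix: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    case: str,
    control: str,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """SAM two-class analysis of a log2 matrix (features x samples).

    ``groups`` maps sample name -> group label.  ``s0=None`` selects the
    fudge factor automatically; ``s0=0`` reduces d to the ordinary pooled
    two-sample t statistic.  Returns a frame with feature_id, d, s, s0,
    q, direction.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    samples = [c for c in matrix.columns if c in groups.index]
    labels = groups.loc[samples]
    keep = labels.isin([case, control])
    samples = [s for s, k in zip(samples, keep) if k]
    labels = labels[keep]
    case_mask = (labels == case).to_numpy()
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise CrossDatasetError("need >=2 samples per group")
    x = matrix[samples].to_numpy(dtype=float)

    d_obs_num_d, s = _d_statistic(x, case_mask, 0.0)
    d_num = d_obs_num_d * s  # recover plain mean difference
    if s0 is None:
        s0 = tusher_s0(d_num, s)
    d_obs, _ = _d_statistic(x, case_mask, s0)

    rng = np.random.default_rng(seed)
    masks = _permutation_masks(len(samples), case_mask, n_perm, rng)
    abs_obs = np.abs(d_obs)
    # observed calls at cut |d_i|: count of |d_obs| >= |d_i|
    order = np.argsort(-abs_obs, kind="mergesort")
    n_feat = x.shape[0]
    called = np.empty(n_feat)
    called[order] = np.arange(1, n_feat + 1)
    # false calls per permutation at each cut
    false_counts = np.empty((masks.shape[0], n_feat))
    sorted_abs = np.sort(abs_obs)
    for mi, mask in enumerate(masks):
        d_perm, _ = _d_statistic(x, mask, s0)
        abs_perm = np.sort(np.abs(d_perm))
        # for each cut c: #{|d_perm| >= c}
        false_counts[mi] = abs_perm.size - np.searchsorted(
            abs_perm, abs_obs, side="left"
        )
    expected_false = np.median(false_counts, axis=0)
    q = expected_false / called
    # monotonize: q non-increasing in |d|
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_final = np.empty(n_feat)
    q_final[order] = np.clip(q_sorted, 0.0, 1.0)
    return pd.DataFrame(
        {
            "feature_id": matrix.index.astype(str),
            "d": d_obs,
            "s": s,
            "s0": s0,
            "q": q_final,
            "direction": np.where(d_obs > 0, "up", np.where(d_obs < 0, "down", "none")),
        }
    ).set_index("feature_id", drop=False)


def harmonize(
    datasets: dict[str, pd.DataFrame],
    join: str = "outer",
) -> pd.DataFrame:
    """Join per-study DE tables by stable gene ID into a concordance matrix.

    Each table needs gene_id, fc (linear fold change), significant.
    Duplicate gene_ids within a study keep the entry with the largest
    |log2 fc|.  A feature is kept only if present in >=2 datasets
    (inner join keeps features present in all).  ``agreement`` is true
    when all significant entries of a feature share a direction.
    """
    if join not in ("inner", "outer"):
        raise CrossDatasetError(f"join must be inner or outer, got {join!r}")
    frames = {}
    for name, tbl in datasets.items():
        missing = {"gene_id", "fc", "significant"} - set(tbl.columns)
        if missing:
            raise CrossDatasetError(f"{name}: missing columns {sorted(missing)}")
        t = tbl.copy()
        t["_abs_l2fc"] = np.abs(np.log2(t["fc"].astype(float)))
        t = (
            t.sort_values("_abs_l2fc", ascending=False)
            .drop_duplicates("gene_id", keep="first")
            .set_index("gene_id")
        )
        frames[name] = t[["fc", "significant"]]
    names = list(frames)
    all_ids: pd.Index = pd.Index([])
    for t in frames.values():
        all_ids = all_ids.union(t.index)
    rows = []
    for gid in all_ids:
        present = [n for n in names if gid in frames[n].index]
        if join == "inner" and len(present) < len(names):
            continue
        if len(present) < 2:
            continue
        row: dict = {"gene_id": gid, "n_datasets": len(present)}
        directions = set()
        for n in names:
            if gid in frames[n].index:
                fc = float(frames[n].loc[gid, "fc"])
                sig = bool(frames[n].loc[gid, "significant"])
                row[f"fc_{n}"] = fc
                row[f"sig_{n}"] = sig
                if sig:
                    directions.add("up" if fc > 1 else "down")
            else:
                row[f"fc_{n}"] = np.nan
                row[f"sig_{n}"] = False
        row["agreement"] = len(directions) == 1
        rows.append(row)
    cols = ["gene_id", "n_datasets"]
    for n in names:
        cols += [f"fc_{n}", f"sig_{n}"]
    cols.append("agreement")
    return pd.DataFrame(rows, columns=cols)
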