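"""Voxel-wise two-sample and paired t-tests.

Cross-sectional designs use the unpaired two-sample t (pooled variance by
default, Welch optional); longitudinal two-timepoint designs use the paired
t, which is exactly the one-sample t on per-subject differences. The sign
convention is group1 - group2 (first label in table order) and A - B for
paired data. Zero-variance voxels follow the t = +/-inf convention and are
flagged rather than erroring.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .results import StatMapResult
from .volio import VoxelMatrix

__all__ = ["unpaired_ttest", "paired_ttest"]


def _finish(name, diff, se, df, tau):
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where((se == 0) & (diff > 0), np.inf, t)
    t = np.where((se == 0) & (diff < 0), -np.inf, t)
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    pval = np.where(np.isinf(t), 0.0, pval)
    degenerate = se == 0
    return StatMapResult(
        term_names=[name],
        beta=diff[:, None],
        se=se[:, None],
        stat=t[:, None],
        pvalue=pval[:, None],
        df_residual=np.broadcast_to(np.asarray(df, float), (tau,)).copy(),
        converged=np.ones(tau, dtype=bool),
        degenerate=degenerate,
        stat_name="t",
    )


def unpaired_ttest(
    matrix: VoxelMatrix,
    groups,
    equal_var: bool = True,
) -> StatMapResult:
    """Per-voxel two-sample t-test between the two label values in ``groups``.

    ``groups`` is a length-n vector with exactly two distinct values; the
    contrast is (first value in row order) minus (second). ``equal_var``
    selects the pooled-variance test (default) or Welch.
    """
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # unique, first-appearance order
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}: {labels!r}")
    a = matrix.data[groups == labels[0]]
    b = matrix.data[groups == labels[1]]
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    diff = a.mean(axis=0) - b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full(matrix.tau, float(n1 + n2 - 2))
    else:
        q1, q2 = v1 / n1, v2 / n2
        se = np.sqrt(q1 + q2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (q1 + q2) ** 2 / (q1**2 / (n1 - 1) + q2**2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, 1.0)
    name = f"{labels[0]}-{labels[1]}"
    return _finish(name, diff, se, df, matrix.tau)


def paired_ttest(
    matrix_a: VoxelMatrix,
    matrix_b: VoxelMatrix,
) -> StatMapResult:
    """Per-voxel paired t-test: one-sample t on A - B differences.

    Rows are aligned by subject id; ids present in only one matrix are an
    error listing the offenders. df = n_pairs - 1.
    """
    ids_a, ids_b = list(matrix_a.subject_ids), list(matrix_b.subject_ids)
    missing = sorted(set(ids_a) ^ set(ids_b))
    if missing:
        raise ValueError(f"unmatched subject ids between timepoints: {missing}")
    if matrix_a.tau != matrix_b.tau:
        raise ValueError("timepoint matrices disagree on voxel count")
    order = [ids_b.index(i) for i in ids_a]
    d = matrix_a.data - matrix_b.data[order]
    n = d.shape[0]
    if n < 2:
        raise ValueError("paired test needs at least 2 pairs")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    return _finish("paired_diff", mean, se, float(n - 1), matrix_a.tau)
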