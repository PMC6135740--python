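"""Per-feature lineage ANOVA, q-values and the shuffled-label background.

The per-feature test uses the nested model of :mod:`rainbowseq.variance`:
F = (SS_lineage/d1) / (SS_resid/d_res) with (d1, d_res) df, testing the null
that the feature shows no between-lineage expression difference. q-values
are Benjamini–Hochberg by default (Storey's pi0-adjusted variant optional).
The background relabels each blastomere's lineage by permuting labels
within its embryo — group sizes are preserved and embryo effects cannot
leak into the lineage term — and reruns the identical test + q pipeline.
The real and background q ensembles are compared with a two-sample
Kolmogorov–Smirnov test and counts below a threshold q*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CellRecord
from .variance import nested_ss_matrix, stage_design

#: two-sample KS p-values below this are numeric underflow, not estimates
P_FLOOR = 2.2e-16


@dataclass
class BackgroundComparison:
    ks_stat: float
    ks_p: float
    n_real: int
    n_shuffled: int
    q_star: float
    n_real_below: int
    n_shuffled_below: int


def anova_lineage(
    y: Sequence[float], embryo: Sequence, lineage: Sequence
) -> tuple[float, float]:
    """Nested-ANOVA F test of the lineage term for one feature.

    Raises ValueError for degenerate input (no residual df, or a constant
    feature with nothing to test); callers treat that as "feature skipped".
    """
    sse, ssl, ssr, d1, d2, d_res = nested_ss_matrix(
        np.asarray(y, dtype=float)[None, :], embryo, lineage
    )
    if d_res <= 0:
        raise ValueError("no residual degrees of freedom")
    if ssr[0] == 0 and ssl[0] == 0:
        raise ValueError("constant feature; F undefined")
    if ssr[0] == 0:
        return float("inf"), 0.0
    f = (ssl[0] / d1) / (ssr[0] / d_res)
    return float(f), float(stats.f.sf(f, d1, d_res))


def anova_matrix(
    Y: np.ndarray, embryo: Sequence, lineage: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised lineage F test; degenerate features get NaN."""
    sse, ssl, ssr, d1, d2, d_res = nested_ss_matrix(Y, embryo, lineage)
    if d_res <= 0:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssl / d1) / (ssr / d_res)
    f[(ssr == 0) & (ssl == 0)] = np.nan
    p = np.where(np.isinf(f), 0.0, stats.f.sf(f, d1, d_res))
    p[np.isnan(f)] = np.nan
    return f, p


def compute_q(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjusted q-values (monotone step-up).

    ``bh``: Benjamini–Hochberg. ``storey``: BH scaled by the pi0 estimate
    pi0 = min(1, 2·mean(p > 0.5)).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0,1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, 2.0 * float((p > 0.5).mean()))
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    return q


def test_features(
    matrix: pd.DataFrame,
    cells: Iterable[CellRecord],
    stage: str,
    expressed_threshold: float = 1.0,
    q_method: str = "bh",
) -> pd.DataFrame:
    """Per-feature lineage test for one stage.

    Features (genes or isoforms) are filtered to FPKM > threshold in ≥1
    resolved cell of the stage; y = log2(FPKM+1). Returns a DataFrame with
    columns feature_id, f_stat, p, q (degenerate features dropped).
    """
    kept, embryo, lineage = stage_design(cells, stage)
    sub = matrix[[c.cell_id for c in kept]]
    expressed = (sub.values > expressed_threshold).any(axis=1)
    sub = sub.loc[expressed]
    if sub.empty:
        return pd.DataFrame(columns=["feature_id", "f_stat", "p", "q"])
    Y = np.log2(sub.values + 1.0)
    f, p = anova_matrix(Y, embryo, lineage)
    ok = ~np.isnan(p)
    frame = pd.DataFrame(
        {"feature_id": sub.index[ok], "f_stat": f[ok], "p": p[ok]}
    )
    frame["q"] = compute_q(frame["p"].values, method=q_method)
    return frame


def shuffle_background(
    matrix: pd.DataFrame,
    cells: Iterable[CellRecord],
    stage: str,
    n_shuffles: int = 1,
    seed: int = 0,
    expressed_threshold: float = 1.0,
    q_method: str = "bh",
    statistic: str = "q",
) -> np.ndarray:
    """Pooled background q-values after relabeling lineages within embryos.

    Each shuffle draws an independent permutation of the lineage labels
    within every embryo (group sizes preserved; the identity permutation is
    allowed) and reruns the full test + q pipeline. Ensembles from all
    shuffles are pooled. ``statistic="p"`` returns raw p-values instead —
    useful for calibration checks, since BH q-values under a global null
    concentrate into a narrow band near 1 whose location fluctuates between
    ensembles, making distribution comparisons on the q scale meaningful
    only in the presence of signal.
    """
    if statistic not in ("q", "p"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    kept, embryo, lineage = stage_design(cells, stage)
    sub = matrix[[c.cell_id for c in kept]]
    expressed = (sub.values > expressed_threshold).any(axis=1)
    sub = sub.loc[expressed]
    if sub.empty:
        return np.array([])
    Y = np.log2(sub.values + 1.0)

    pooled = []
    for _ in range(n_shuffles):
        shuffled = lineage.copy()
        for e in np.unique(embryo):
            idx = np.where(embryo == e)[0]
            shuffled[idx] = rng.permutation(shuffled[idx])
        f, p = anova_matrix(Y, embryo, shuffled)
        p = p[~np.isnan(p)]
        pooled.append(p if statistic == "p" else compute_q(p, method=q_method))
    return np.concatenate(pooled)


def compare_distributions(
    real_q: Sequence[float],
    shuffled_q: Sequence[float],
    q_star: float = 0.01,
) -> BackgroundComparison:
    """Two-sample KS comparison of real vs background q-values.

    ``ks_p`` is floored at 2.2e-16 when the test underflows (the floor is a
    reporting convention, not an estimate).
    """
    real = np.asarray(list(real_q), dtype=float)
    bg = np.asarray(list(shuffled_q), dtype=float)
    if real.size == 0 or bg.size == 0:
        raise ValueError("empty q-value ensemble")
    ks = stats.ks_2samp(real, bg)
    ks_p = float(ks.pvalue) if ks.pvalue > P_FLOOR else P_FLOOR
    return BackgroundComparison(
        ks_stat=float(ks.statistic), ks_p=ks_p,
        n_real=real.size, n_shuffled=bg.size, q_star=q_star,
        n_real_below=int((real < q_star).sum()),
        n_shuffled_below=int((bg < q_star).sum()),
    )
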