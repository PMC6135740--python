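"""Per-gene nested variance partitioning and the ratio statistic r_g.

For gene g with per-cell log expression y, a Gaussian linear model with
embryo as a factor and division lineage nested within embryo gives
sequential (type-I) sums of squares

    SS_embryo  = Σ_i n_i  (ȳ_i  − ȳ)²        (embryo means vs grand mean)
    SS_lineage = Σ_i Σ_j n_ij (ȳ_ij − ȳ_i)²  (lineage-within-embryo means)
    SS_resid   = Σ (y − ȳ_ij)²

and the ratio r_g = SS_lineage / (SS_lineage + SS_embryo). Lineage is
nested because the A/B labels are arbitrary per embryo. Under a balanced
global null (no embryo or lineage effects, Gaussian noise) r_g follows
Beta(d1/2, d2/2) with d1 = E lineage-within-embryo df and d2 = E − 1 embryo
df for E embryos; heavier-than-Beta right tails of the empirical
distribution R across genes indicate a transcriptome-wide lineage effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CellRecord

DEFAULT_BETAS = [(1.0, 3.0), (2.0, 2.0), (5.0, 5.0)]
DEFAULT_DELTAS = [0.05, 0.1, 0.2]


@dataclass
class VariancePartition:
    gene_id: str
    ss_lineage: float
    ss_embryo: float
    ss_residual: float
    r: Optional[float]


@dataclass
class BetaComparison:
    alpha: float
    beta: float
    ks_distance: float
    tail_pairs: list[tuple[float, float, float]]  # (delta, empirical, beta)
    qq_points: list[tuple[float, float]]          # (beta quantile, empirical)


def _design(embryo: Sequence, lineage: Sequence):
    embryo = np.asarray(embryo)
    lineage = np.asarray(lineage)
    if embryo.shape != lineage.shape:
        raise ValueError("embryo and lineage labels differ in length")
    uniq_e = np.unique(embryo)
    if len(uniq_e) < 2:
        raise ValueError("need at least 2 embryos")
    for e in uniq_e:
        lins = set(lineage[embryo == e])
        if lins != {"A", "B"}:
            raise ValueError(f"embryo {e!r} lacks both lineages (has {lins})")
    # integer codes for embryo and embryo×lineage cells
    e_codes = np.searchsorted(uniq_e, embryo)
    cell_key = e_codes * 2 + (lineage == "B")
    return e_codes, cell_key, len(uniq_e)


def nested_ss_matrix(
    Y: np.ndarray, embryo: Sequence, lineage: Sequence
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int, int]:
    """Vectorised nested decomposition of many features at once.

    ``Y`` is features × cells. Returns ``(ss_embryo, ss_lineage, ss_resid,
    d1, d2, d_res)`` with the df of the balanced nested design: d1 = E,
    d2 = E − 1, d_res = N − 2E.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    e_codes, cell_key, E = _design(embryo, lineage)
    N = Y.shape[1]

    grand = Y.mean(axis=1, keepdims=True)

    n_e = np.bincount(e_codes, minlength=E).astype(float)
    sum_e = np.zeros((Y.shape[0], E))
    for e in range(E):
        sum_e[:, e] = Y[:, e_codes == e].sum(axis=1)
    mean_e = sum_e / n_e

    keys = np.unique(cell_key)
    n_c = np.array([(cell_key == k).sum() for k in keys], dtype=float)
    mean_c = np.column_stack([Y[:, cell_key == k].mean(axis=1) for k in keys])
    parent = keys // 2  # embryo of each embryo×lineage cell

    ss_embryo = (n_e * (mean_e - grand) ** 2).sum(axis=1)
    ss_lineage = (n_c * (mean_c - mean_e[:, parent]) ** 2).sum(axis=1)
    fitted = np.zeros_like(Y)
    for j, k in enumerate(keys):
        fitted[:, cell_key == k] = mean_c[:, [j]]
    ss_resid = ((Y - fitted) ** 2).sum(axis=1)

    d1, d2, d_res = E, E - 1, N - 2 * E
    return ss_embryo, ss_lineage, ss_resid, d1, d2, d_res


def decompose_gene(
    y: Sequence[float], embryo: Sequence, lineage: Sequence,
    gene_id: str = "gene",
) -> VariancePartition:
    """Nested decomposition of one gene; r is None when SS_lineage +
    SS_embryo is 0 (e.g. a constant gene)."""
    sse, ssl, ssr, *_ = nested_ss_matrix(
        np.asarray(y, dtype=float)[None, :], embryo, lineage
    )
    denom = ssl[0] + sse[0]
    r = float(ssl[0] / denom) if denom > 0 else None
    return VariancePartition(gene_id, float(ssl[0]), float(sse[0]),
                             float(ssr[0]), r)


def stage_design(
    cells: Iterable[CellRecord], stage: str
) -> tuple[list[CellRecord], np.ndarray, np.ndarray]:
    """Restrict cells to one stage with resolved lineages, dropping embryos
    that do not retain both lineages (with a warning)."""
    kept = [c for c in cells if c.stage == stage and c.lineage in ("A", "B")]
    by_embryo: dict[str, set] = {}
    for c in kept:
        by_embryo.setdefault(c.embryo_id, set()).add(c.lineage)
    bad = {e for e, lins in by_embryo.items() if lins != {"A", "B"}}
    if bad:
        warnings.warn(f"dropping embryos lacking both lineages: {sorted(bad)}")
        kept = [c for c in kept if c.embryo_id not in bad]
    embryo = np.array([c.embryo_id for c in kept])
    lineage = np.array([c.lineage for c in kept])
    return kept, embryo, lineage


def empirical_R(
    matrix: pd.DataFrame,
    cells: Iterable[CellRecord],
    stage: str,
    expressed_threshold: float = 1.0,
) -> pd.Series:
    """Compute r_g for every expressed gene of one stage.

    Genes must have FPKM > ``expressed_threshold`` in at least one of the
    stage's resolved cells; y = log2(FPKM + 1). Genes with undefined r are
    excluded. Returns a Series indexed by gene id, in gene order.
    """
    kept, embryo, lineage = stage_design(cells, stage)
    sub = matrix[[c.cell_id for c in kept]]
    expressed = (sub.values > expressed_threshold).any(axis=1)
    sub = sub.loc[expressed]
    if sub.empty:
        return pd.Series(dtype=float, name="r")
    Y = np.log2(sub.values + 1.0)
    sse, ssl, _, *_ = nested_ss_matrix(Y, embryo, lineage)
    denom = ssl + sse
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, ssl / denom, np.nan)
    out = pd.Series(r, index=sub.index, name="r")
    return out.dropna()


def null_beta_params(n_embryos: int) -> tuple[float, float]:
    """Beta(d1/2, d2/2) parameters of r_g under the balanced global null."""
    return n_embryos / 2.0, (n_embryos - 1) / 2.0


def compare_to_beta(
    r_values: Sequence[float],
    params: Sequence[tuple[float, float]] = tuple(DEFAULT_BETAS),
    deltas: Sequence[float] = tuple(DEFAULT_DELTAS),
) -> list[BetaComparison]:
    """Compare the empirical distribution R against Beta references.

    For each (a, b): the one-sample KS distance, right-tail probabilities
    P(R ≥ 1 − δ) empirical vs analytic, and Q-Q points at percentiles 1–99.
    """
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise ValueError("compare_to_beta: empty r_values")
    out = []
    pct = np.arange(1, 100) / 100.0
    emp_q = np.quantile(r, pct)
    for a, b in params:
        dist = stats.beta(a, b)
        ks = stats.kstest(r, dist.cdf).statistic
        tails = [
            (float(d), float((r >= 1 - d).mean()), float(dist.sf(1 - d)))
            for d in deltas
        ]
        qq = list(zip(dist.ppf(pct).tolist(), emp_q.tolist()))
        out.append(BetaComparison(a, b, float(ks), tails, qq))
    return out
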