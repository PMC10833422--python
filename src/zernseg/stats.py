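"""Statistical comparison of model families and hyperparameters.

Wilcoxon signed-rank (paired, two-sided) compares the two architectures'
metric columns; Spearman rank correlation quantifies how validation
metrics scale with training-data size and batch size.  P-values below
0.05 are flagged significant.

Small samples use exact null distributions: full sign enumeration for the
Wilcoxon statistic at n <= 12 and full permutation of one variable for
Spearman at n <= 8; larger samples fall back to the standard normal
approximations (via scipy).  Rank ties receive average ranks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ContractError, DegenerateTestError

ALPHA = 0.05


def wilcoxon_signed_rank(a, b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Returns ``(W+, p)`` where ``W+`` is the positive-rank sum.  Zero
    differences are dropped (standard practice); if all differences are
    zero the test is degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("paired samples must be equal-length 1D arrays")
    if len(a) < 5:
        raise ContractError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = len(d)
    if n <= exact_max_n:
        # exact null: every sign assignment equally likely
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
        w_all = np.where(signs, ranks, 0.0).sum(axis=1)
        p_le = float((w_all <= w_plus + 1e-12).mean())
        p_ge = float((w_all >= w_plus - 1e-12).mean())
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        _, p = sps.wilcoxon(d, alternative="two-sided", method="approx")
        p = float(p)
    return w_plus, p


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_rank(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    Exact p by full permutation of ``y`` for n <= 8; the t-approximation
    (scipy) above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be equal-length 1D arrays")
    if len(x) < 4:
        raise ContractError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("constant input: rank correlation undefined")
    rho = _spearman_rho(x, y)
    n = len(x)
    if n <= exact_max_n:
        ry = sps.rankdata(y)
        rhos = np.array([_spearman_rho(x, ry[list(p)]) for p in permutations(range(n))])
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


REQUIRED_COLUMNS = ("arch", "batch", "train_size", "val_dice", "val_loss")


def grid_analysis(table: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Summarize an experiment grid table.

    Per (architecture, batch size): Spearman rho of training size versus
    validation Dice and loss.  Across architectures: Wilcoxon signed-rank
    on the metric columns, paired by (batch, train_size[, seed]).
    Returns a JSON-serializable summary with significance flags.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ConfigurationError(f"grid table missing column '{col}'")
    archs = sorted(table["arch"].unique())
    cells = table.groupby(["arch", "batch"])["train_size"].nunique()
    if cells.nunique() != 1:
        raise ConfigurationError("incomplete grid: unequal train-size coverage per cell")

    correlations = []
    for (arch, batch), sub in table.groupby(["arch", "batch"]):
        sub = sub.sort_values("train_size")
        for metric in ("val_dice", "val_loss"):
            try:
                rho, p = spearman_rank(sub["train_size"].to_numpy(), sub[metric].to_numpy())
                entry = {"rho": rho, "p": p, "significant": bool(p < alpha)}
            except DegenerateTestError as exc:
                entry = {"rho": None, "p": None, "significant": False, "note": str(exc)}
            entry.update({"arch": arch, "batch": int(batch), "metric": metric})
            correlations.append(entry)

    between = {}
    if len(archs) == 2:
        keys = ["batch", "train_size"] + (["seed"] if "seed" in table.columns else [])
        merged = pd.merge(
            table[table["arch"] == archs[0]],
            table[table["arch"] == archs[1]],
            on=keys,
            suffixes=("_a", "_b"),
        ).sort_values(keys)
        for metric in ("val_dice", "val_loss"):
            try:
                w, p = wilcoxon_signed_rank(
                    merged[f"{metric}_a"].to_numpy(), merged[f"{metric}_b"].to_numpy()
                )
                between[metric] = {"statistic": w, "p": p, "significant": bool(p < alpha)}
            except DegenerateTestError:
                between[metric] = {"statistic": None, "p": None, "significant": False,
                                   "note": "no difference"}
    return {"architectures": archs, "correlations": correlations,
            "between_architectures": between, "alpha": alpha}
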