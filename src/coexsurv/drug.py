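"""Expression versus drug-response correlation across cell lines.

Correlates one gene's expression with the per-line area under the
dose-response curve (AUC; higher = more resistant) for a chosen drug,
and flags lines discordant with the fitted trend (e.g. high RNA but
unexpectedly low response) via standardized least-squares residuals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_OVERLAP = 4


def _overlap(expr: pd.Series, responses: pd.DataFrame, drug: str, metric: str):
    sub = responses[responses["drug"] == drug]
    if sub.empty:
        raise ValueError(f"drug {drug!r} not present in the response table")
    resp = sub.set_index("cell_line")[metric]
    common = [c for c in expr.index if c in resp.index]
    n_dropped = len(expr) - len(common)
    if n_dropped:
        logger.info("%d cell lines lack %s response for %s", n_dropped, metric, drug)
    if len(common) < MIN_OVERLAP:
        raise ValueError(
            f"only {len(common)} overlapping cell lines for {drug}; need >= {MIN_OVERLAP}"
        )
    return expr.loc[common].astype(float), resp.loc[common].astype(float)


def correlate_drug(
    expr: pd.Series,
    responses: pd.DataFrame,
    drug: str,
    method: str = "pearson",
    metric: str = "auc",
) -> tuple[float, float, int]:
    """Correlation (r, two-sided p, n) between expression and drug response.

    ``expr`` is indexed by cell line; the intersection with the response
    table is used. ``metric`` names the response column (AUC by default;
    an IC50 column works the same way).
    """
    x, y = _overlap(expr, responses, drug, metric)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p), len(x)


def flag_outlier_lines(
    expr: pd.Series,
    responses: pd.DataFrame,
    drug: str,
    metric: str = "auc",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Standardized residuals of response on expression, flagging |resid| > 2.

    A flagged line departs from the cohort trend — the discordant-line
    pattern (e.g. high transcript yet low response). Returns a DataFrame
    (cell_line, expression, response, residual, flagged).
    """
    x, y = _overlap(expr, responses, drug, metric)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sd = resid.std(ddof=2)
    if sd == 0:
        std_resid = pd.Series(np.zeros(len(resid)), index=resid.index)
    else:
        std_resid = resid / sd
    return pd.DataFrame({
        "cell_line": x.index,
        "expression": x.to_numpy(),
        "response": y.to_numpy(),
        "residual": std_resid.to_numpy(),
        "flagged": np.abs(std_resid.to_numpy()) > threshold,
    })
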