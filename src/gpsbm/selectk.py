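"""Model selection over the maximum community count k.

Each candidate k is fit in full; the report carries the number of occupied
communities at the posterior mode and a deviance information criterion
(DIC with the variance-based effective-parameter count, p_D = var(D)/2 —
convenient here because the deviance draws are already at hand and no
plug-in over the discrete labels is needed). The chosen k is the smallest
whose occupied count is strictly below k: the data are then demonstrably
well represented by fewer communities than allowed, so the cap is not
binding. If every candidate saturates, the largest k is returned with a
warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .panel import NetworkPanel
from .mcmc import MCMCConfig, PriorSpec, fit_tsbm
from .summarize import relabel_by_size

__all__ = ["select_k"]

logger = logging.getLogger(__name__)


def select_k(
    panel: NetworkPanel,
    k_grid=(6, 8, 10, 12),
    mcmc: MCMCConfig = MCMCConfig(),
    priors: PriorSpec = PriorSpec(),
):
    """Fit every k in ``k_grid`` and choose the smallest non-saturated one.

    Returns (chosen_k, report) where report maps k to a dict with
    ``occupied_k``, ``mean_loglik``, ``dic`` and the fit summary.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    report = {}
    for k in k_grid:
        trace = fit_tsbm(panel, k, mcmc, priors)
        summary = relabel_by_size(trace)
        deviance = -2.0 * trace.loglik
        dic = float(deviance.mean() + deviance.var() / 2.0)
        report[k] = {
            "occupied_k": summary.occupied_k,
            "mean_loglik": float(trace.loglik.mean()),
            "dic": dic,
            "summary": summary,
        }
    for k in k_grid:
        if report[k]["occupied_k"] < k:
            return k, report
    logger.warning(
        "every candidate k saturated its community budget; returning the "
        "largest (k=%d) — consider extending the grid", k_grid[-1]
    )
    return k_grid[-1], report
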