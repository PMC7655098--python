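"""Partial-regression (added-variable) plots for the fitted models.

The headline figure of this analysis family plots the residuals of the
outcome on all control variables against the residuals of the predictor of
interest on the same controls — the slope of that scatter is exactly the
predictor's coefficient in the full model.
"""

from __future__ import annotations

import numpy as np

from .regression import EuthymiaResults


def plot_partial_regression(results: EuthymiaResults, predictor: str, ax=None):
    """Added-variable plot of one predictor, with the partial fit line.

    Requires matplotlib (optional dependency); returns the axis.
    """
    import matplotlib.pyplot as plt

    model = results.model
    if predictor not in model.exog_names:
        raise ValueError(f"{predictor!r} not among model terms {model.exog_names}")
    j = model.exog_names.index(predictor)
    others = np.delete(model._X, j, axis=1)
    Xo = np.column_stack([np.ones(len(model.frame)), others])

    def _resid(v: np.ndarray) -> np.ndarray:
        beta = np.linalg.lstsq(Xo, v, rcond=None)[0]
        return v - Xo @ beta

    x_res = _resid(model._X[:, j])
    y_res = _resid(model.endog)

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x_res, y_res, s=28, alpha=0.8, edgecolor="k", linewidth=0.4)
    slope = float(results.params[predictor])
    grid = np.linspace(x_res.min(), x_res.max(), 50)
    ax.plot(grid, slope * grid, color="firebrick")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"{predictor} | controls")
    ax.set_ylabel(f"{model.spec.outcome} | controls")
    ax.set_title(f"{model.spec.name}: partial slope = {slope:.3f}")
    return ax
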