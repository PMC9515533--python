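"""Goodness-of-fit quantities: predictions, conditional weighted residuals,
and residual-distribution summaries.

Only the plotted *quantities* are computed here (tables suitable for
goodness-of-fit and Q-Q/density plots); figure rendering is out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh

from .data import Dataset
from .errors import DiagnosticError
from .estimate import FitResult, _Compiled, _predict, _tv_arrays
from .popmodel import PopulationModel

_G_STEP = 1e-4  # finite-difference step for df/deta


def predictions(dataset: Dataset, model: PopulationModel, fit: FitResult) -> pd.DataFrame:
    """Per-observation table: ID, TIME, DV, PRED (eta=0), IPRED (eta-hat)."""
    c = _Compiled(dataset)
    tvcl, tvv, ka = _tv_arrays(model, c)
    missing = [sid for sid in c.ids if sid not in fit.eta]
    if missing:
        raise DiagnosticError(f"no empirical Bayes eta for subjects {missing}")
    eta = np.array([fit.eta[sid] for sid in c.ids])
    pred, ok0 = _predict(c, tvcl, tvv, ka, np.zeros(c.n_sub))
    ipred, ok1 = _predict(c, tvcl, tvv, ka, eta)
    if not (ok0.all() and ok1.all()):
        raise DiagnosticError("degenerate kinetics while computing predictions")
    times = [t for s in dataset.subjects for t, _ in s.observations]
    ids = [s.id for s in dataset.subjects for _ in s.observations]
    return pd.DataFrame(
        {"ID": ids, "TIME": times, "DV": c.y, "PRED": pred, "IPRED": ipred}
    )


def cwres(dataset: Dataset, model: PopulationModel, fit: FitResult) -> np.ndarray:
    """FOCE-I conditional weighted residuals, one per observation.

    Per subject the residual vector ``DV - f(eta_hat) + G*eta_hat`` (first-order
    linearization of the model about the conditional mode) is standardized by
    the inverse symmetric square root of ``G omega^2 G' + Sigma_res`` with
    ``G = df/deta`` at ``eta_hat``.  With omega = 0 and additive error this
    reduces to ``(DV - PRED)/sigma1`` elementwise.
    """
    c = _Compiled(dataset)
    tvcl, tvv, ka = _tv_arrays(model, c)
    missing = [sid for sid in c.ids if sid not in fit.eta]
    if missing:
        raise DiagnosticError(f"no empirical Bayes eta for subjects {missing}")
    eta = np.array([fit.eta[sid] for sid in c.ids])
    omega2 = model.iiv.sd ** 2

    f, ok = _predict(c, tvcl, tvv, ka, eta)
    fp, okp = _predict(c, tvcl, tvv, ka, eta + _G_STEP)
    fm, okm = _predict(c, tvcl, tvv, ka, eta - _G_STEP)
    if not (ok.all() and okp.all() and okm.all()):
        raise DiagnosticError("degenerate kinetics while computing CWRES")
    G = (fp - fm) / (2 * _G_STEP)
    g2 = np.asarray(model.residual.variance(f), dtype=float)

    out = np.empty(c.n_obs)
    for i in range(c.n_sub):
        sel = c.obs_sub == i
        r = c.y[sel] - f[sel] + G[sel] * eta[i]
        cov = omega2 * np.outer(G[sel], G[sel]) + np.diag(g2[sel])
        vals, vecs = eigh(cov)
        if np.any(vals <= 0):
            raise DiagnosticError(f"singular residual covariance for subject {c.ids[i]}")
        inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
        out[sel] = inv_sqrt @ r
    if not np.all(np.isfinite(out)):
        raise DiagnosticError("non-finite CWRES")
    return out


def gof_table(dataset: Dataset, model: PopulationModel, fit: FitResult) -> pd.DataFrame:
    """Full goodness-of-fit record table: ID, TIME, DV, PRED, IPRED, CWRES."""
    table = predictions(dataset, model, fit)
    table["CWRES"] = cwres(dataset, model, fit)
    return table


def residual_distribution_summary(residuals, n_grid: int = 200) -> dict:
    """Density-curve data and normal Q-Q pairs for a residual vector.

    Kernel density uses Silverman's bandwidth on a grid of ``n_grid`` points
    spanning mean +/- 4 SD; Q-Q pairs match empirical order statistics to
    standard-normal quantiles at the (i - 0.5)/n probability points.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 1 or r.size < 10:
        raise DiagnosticError("need at least 10 residuals for a distribution summary")
    sd = float(np.std(r))
    if sd == 0.0:
        raise DiagnosticError("residuals are constant; distribution is degenerate")
    mean = float(np.mean(r))
    grid = np.linspace(mean - 4 * sd, mean + 4 * sd, n_grid)
    kde = stats.gaussian_kde(r, bw_method="silverman")
    density = kde(grid)
    q = (np.arange(1, r.size + 1) - 0.5) / r.size
    return {
        "grid": grid,
        "density": density,
        "qq_theoretical": stats.norm.ppf(q),
        "qq_empirical": np.sort(r),
    }
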