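"""Phase decomposition of order-parameter distributions.

A heterogeneous membrane's per-carbon order distributions are modelled as a
convex mixture of reference single-phase distributions (gel, liquid-ordered,
liquid-disordered): minimize ``|| target - sum_i f_i ref_i ||^2`` over the
probability simplex (f_i >= 0, sum f_i = 1), stacking the per-carbon
histograms into one vector with equal weight per carbon.

The reported error is L1-relative over all carbon-bin cells,
``100 * sum|target - fitted| / sum(target)`` (percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .order import OrderDistribution


@dataclass
class MixtureFit:
    labels: list[str]
    fractions: np.ndarray
    fitted: OrderDistribution
    error_percent: float
    objective: float

    def as_dict(self) -> dict:
        return {
            "fractions": {lb: float(f) for lb, f in zip(self.labels, self.fractions)},
            "error_percent": float(self.error_percent),
        }


def _stack(dist: OrderDistribution) -> np.ndarray:
    return dist.histograms.ravel()


def fit_mixture(
    target: OrderDistribution,
    refs: list[OrderDistribution],
    labels: list[str] | None = None,
) -> MixtureFit:
    """Constrained least-squares mixture of reference distributions.

    The sum-to-one constraint is enforced exactly (SLSQP on the simplex); a
    tiny ridge (1e-10) breaks ties toward the minimum-norm fraction vector
    when references are collinear.
    """
    if len(refs) < 2:
        raise ValueError("need at least two reference distributions")
    for r in refs:
        if not target.same_binning(r):
            raise ValueError("reference binning/carbon list does not match target")
    b = _stack(target)
    if not np.any(b):
        raise ValueError("degenerate all-zero target distribution")
    A = np.column_stack([_stack(r) for r in refs])
    m = A.shape[1]
    ridge = 1e-10

    def obj(f):
        r = A @ f - b
        return float(r @ r + ridge * f @ f)

    def grad(f):
        return 2.0 * (A.T @ (A @ f - b)) + 2.0 * ridge * f

    x0 = np.full(m, 1.0 / m)
    res = optimize.minimize(
        obj, x0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0,
                      "jac": lambda f: np.ones_like(f)}],
        options={"maxiter": 500, "ftol": 1e-16},
    )
    f = np.clip(res.x, 0.0, None)
    f /= f.sum()
    fitted_rows = (A @ f).reshape(target.histograms.shape)
    # renormalize per carbon only to absorb float error; mixture of normalized
    # rows is itself normalized
    fitted_rows /= fitted_rows.sum(axis=1, keepdims=True)
    fitted = OrderDistribution(
        list(target.carbons), target.bin_edges, fitted_rows,
        provenance={"mixture_of": labels or [f"ref{k}" for k in range(m)]},
    )
    err = fit_error(target, fitted)
    return MixtureFit(
        labels=labels or [f"ref{k}" for k in range(m)],
        fractions=f,
        fitted=fitted,
        error_percent=err,
        objective=float(obj(f)),
    )


def fit_error(target: OrderDistribution, fitted: OrderDistribution | np.ndarray) -> float:
    """L1-relative deviation in percent over all carbon-bin cells."""
    t = target.histograms
    ft = fitted.histograms if isinstance(fitted, OrderDistribution) else np.asarray(fitted)
    if t.shape != ft.shape:
        raise ValueError("target and fitted distributions have different binning")
    return float(100.0 * np.abs(t - ft).sum() / t.sum())
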