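"""Type I / type II functional divergence between clade pairs.

Type I (rate shift) detection uses a two-state mixture over alignment
columns.  Under the null state a column has one rate λ ~ Gamma(α, β) shared
by both clades, and the two clade counts are conditionally Poisson with means
λ·tA and λ·tB (tA, tB the clade tree lengths); marginally this is a
positively correlated pair with negative-binomial margins.  Under the
divergent state each clade draws its own independent rate from the same
gamma.  The mixture weight θ is the coefficient of functional divergence:
the expected fraction of sites whose rate shifted between the clades.  Both
per-site marginals have closed forms, so the likelihood is exact and cheap:

    log m0(xA,xB) = α·log β + lnΓ(xA+xB+α) − lnΓ(α) − lnΓ(xA+1) − lnΓ(xB+1)
                    + xA·log tA + xB·log tB − (xA+xB+α)·log(tA+tB+β)
    log m1(xA,xB) = log nb(xA; tA) + log nb(xB; tB)
    log nb(x; t)  = α·log β + lnΓ(x+α) − lnΓ(α) − lnΓ(x+1)
                    + x·log t − (x+α)·log(t+β)

Counts may be real-valued (multiple-hit corrected); the gamma-function form
of the Poisson mass extends smoothly to non-integer x.

Type II (preference shift) sites are called deterministically: the two clade
root states fall in different radical groups (charge / hydrophobicity
classes) while both clades are conserved at the column; θ_II is the
proportion of such columns among columns conserved in both clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .core_io import AMINO_ACIDS, GAP_CODE, InputError, MultipleAlignment

# radical property groups; a substitution crossing a group boundary is radical
RADICAL_GROUPS: dict[str, str] = {
    "positive": "KRH",
    "negative": "DE",
    "hydrophilic": "STNQCGP",
    "hydrophobic": "AILMFWVY",
}

GROUP_OF = np.full(21, -1, dtype=np.int8)
for _gi, _members in enumerate(RADICAL_GROUPS.values()):
    for _aa in _members:
        GROUP_OF[AMINO_ACIDS.index(_aa)] = _gi

SITE_CLASSES = ("type0", "typeI", "typeII", "none")


def radical_group(code: int) -> str:
    """Name of the radical group of an amino-acid code (0..19)."""
    gi = GROUP_OF[code]
    if gi < 0:
        raise InputError(f"no radical group for state code {code}")
    return list(RADICAL_GROUPS)[gi]


@dataclass
class ThetaEstimate:
    """Fitted coefficient of functional divergence for one clade pair."""

    theta: float
    kind: str  # "typeI" | "typeII"
    alpha: float | None = None
    beta: float | None = None
    log_likelihood: float | None = None
    standard_error: float = float("nan")
    boundary: bool = False
    converged: bool = True


def _log_marginals(
    x_a: np.ndarray, x_b: np.ndarray, t_a: float, t_b: float,
    alpha: float, beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(log m0, log m1) per column; x may be real-valued (corrected counts)."""
    base = alpha * np.log(beta) - gammaln(alpha)
    lfact = gammaln(x_a + 1.0) + gammaln(x_b + 1.0)
    l0 = (
        base
        + gammaln(x_a + x_b + alpha)
        - lfact
        + x_a * np.log(t_a)
        + x_b * np.log(t_b)
        - (x_a + x_b + alpha) * np.log(t_a + t_b + beta)
    )

    def lnb(x, t):
        return (
            base
            + gammaln(x + alpha)
            - gammaln(x + 1.0)
            + x * np.log(t)
            - (x + alpha) * np.log(t + beta)
        )

    return l0, lnb(x_a, t_a) + lnb(x_b, t_b)


def mixture_loglik(
    theta: float, alpha: float, beta: float,
    x_a: np.ndarray, x_b: np.ndarray, t_a: float, t_b: float,
) -> float:
    l0, l1 = _log_marginals(x_a, x_b, t_a, t_b, alpha, beta)
    with np.errstate(divide="ignore"):
        terms = np.logaddexp(np.log1p(-theta) + l0, np.log(theta) + l1)
    return float(terms.sum())


_THETA_STARTS = (0.1, 0.3, 0.5, 0.7, 0.9)


def fit_type_I(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    t_a: float,
    t_b: float,
    min_columns: int = 30,
) -> ThetaEstimate:
    """Maximum-likelihood fit of (θ, α, β) for one clade pair.

    Bounded quasi-Newton (L-BFGS-B on logit/log transformed parameters) from
    five deterministic starts on a fixed θ grid; the start with the best
    final likelihood wins.  The standard error of θ comes from the observed
    information (finite-difference Hessian at the optimum); boundary
    estimates (θ̂ ≈ 0 or 1) are flagged and given no standard error.
    """
    x_a = np.asarray(counts_a, dtype=float)
    x_b = np.asarray(counts_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise InputError("count vectors must cover the same columns")
    if x_a.size < min_columns:
        raise InputError(
            f"type I fit needs at least {min_columns} columns, got {x_a.size}"
        )
    if t_a <= 0 or t_b <= 0:
        raise InputError("clade tree lengths must be positive")
    if (x_a < 0).any() or (x_b < 0).any():
        raise InputError("negative substitution counts")

    mean_rate = max(float((x_a + x_b).mean() / (t_a + t_b)), 1e-3)

    def nll(u: np.ndarray) -> float:
        theta = expit(u[0])
        alpha = np.exp(u[1])
        beta = np.exp(u[2])
        if not np.isfinite(theta * alpha * beta):
            return 1e12
        return -mixture_loglik(theta, alpha, beta, x_a, x_b, t_a, t_b)

    best = None
    bounds = [(-12.0, 12.0), (-6.0, 6.0), (-9.0, 9.0)]
    for th0 in _THETA_STARTS:
        u0 = np.array([logit(th0), 0.0, np.log(1.0 / mean_rate)])
        res = minimize(nll, u0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise InputError("type I mixture fit failed to converge")

    theta = float(expit(best.x[0]))
    alpha = float(np.exp(best.x[1]))
    beta = float(np.exp(best.x[2]))
    ll = -float(best.fun)
    boundary = theta < 1e-4 or theta > 1 - 1e-4
    se = float("nan")
    if not boundary:
        se = _theta_standard_error(theta, alpha, beta, x_a, x_b, t_a, t_b)
    return ThetaEstimate(
        theta=theta, kind="typeI", alpha=alpha, beta=beta,
        log_likelihood=ll, standard_error=se, boundary=boundary,
        converged=bool(best.success),
    )


def _theta_standard_error(theta, alpha, beta, x_a, x_b, t_a, t_b) -> float:
    p = np.array([theta, alpha, beta])
    h = np.maximum(1e-5, 1e-4 * np.abs(p))

    def f(q):
        th = min(max(q[0], 1e-9), 1 - 1e-9)
        if q[1] <= 0 or q[2] <= 0:
            return np.inf
        return -mixture_loglik(th, q[1], q[2], x_a, x_b, t_a, t_b)

    hess = np.empty((3, 3))
    f0 = f(p)
    for i in range(3):
        for j in range(i, 3):
            ei = np.zeros(3); ei[i] = h[i]
            ej = np.zeros(3); ej[j] = h[j]
            if i == j:
                val = (f(p + ei) - 2 * f0 + f(p - ei)) / h[i] ** 2
            else:
                val = (
                    f(p + ei + ej) - f(p + ei - ej) - f(p - ei + ej) + f(p - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    try:
        cov = np.linalg.inv(hess)
        var = cov[0, 0]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


def type_I_posteriors(
    fit: ThetaEstimate,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    t_a: float,
    t_b: float,
) -> pd.DataFrame:
    """Per-column posterior probability of rate shift, plus rate direction.

    Direction orders the clade pair by observed per-length rate x/t:
    (slow, fast).  Returned frame: column, posterior, slow_is_a.
    """
    x_a = np.asarray(counts_a, dtype=float)
    x_b = np.asarray(counts_b, dtype=float)
    l0, l1 = _log_marginals(x_a, x_b, t_a, t_b, fit.alpha, fit.beta)
    with np.errstate(divide="ignore"):
        num = np.log(max(fit.theta, 1e-300)) + l1
        den = np.logaddexp(np.log1p(-min(fit.theta, 1 - 1e-300)) + l0, num)
    post = np.exp(num - den)
    return pd.DataFrame(
        {
            "column": np.arange(1, x_a.size + 1),
            "posterior": post,
            "slow_is_a": x_a / t_a <= x_b / t_b,
        }
    )


def classify_type_II(
    root_a: np.ndarray,
    root_b: np.ndarray,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    conservation_ceiling: float = 0.5,
) -> tuple[np.ndarray, ThetaEstimate]:
    """Flag columns with a radical, fixed between-clade difference.

    A column is type II iff the reconstructed root states of the two clades
    lie in different radical groups and the corrected within-clade counts are
    at most ``conservation_ceiling`` in both clades.  θ_II is estimated as
    the proportion of type II columns among columns conserved in both clades
    (a deterministic proportion, not a likelihood fit — reported as such).
    """
    root_a = np.asarray(root_a)
    root_b = np.asarray(root_b)
    x_a = np.asarray(counts_a, dtype=float)
    x_b = np.asarray(counts_b, dtype=float)
    valid = (GROUP_OF[root_a] >= 0) & (GROUP_OF[root_b] >= 0)
    conserved = (x_a <= conservation_ceiling) & (x_b <= conservation_ceiling) & valid
    flags = conserved & (GROUP_OF[root_a] != GROUP_OF[root_b])
    n_cons = int(conserved.sum())
    theta = float(flags.sum() / n_cons) if n_cons else float("nan")
    return flags, ThetaEstimate(theta=theta, kind="typeII")


def clade_consensus(aln: MultipleAlignment, leaf_ids: list[str]) -> np.ndarray:
    """Per-column consensus residue code within a clade (-1 if all gaps)."""
    enc = aln.subalignment(sorted(leaf_ids)).encoded()
    out = np.full(aln.n_cols, -1, dtype=np.int8)
    for j in range(aln.n_cols):
        col = enc[:, j]
        col = col[col != GAP_CODE]
        if col.size:
            out[j] = np.argmax(np.bincount(col, minlength=20))
    return out


def classify_sites(
    posteriors: pd.DataFrame,
    type2_flags: np.ndarray,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    consensus_a: np.ndarray,
    consensus_b: np.ndarray,
    clade_a: str,
    clade_b: str,
    cutoff: float = 0.90,
) -> pd.DataFrame:
    """Combine type I posteriors and type II flags into per-site classes.

    Precedence: typeII (radical fixed difference — the stronger statement)
    over typeI (posterior above cutoff) over type0 (zero corrected counts in
    both clades with identical consensus residue); remainder ``none``.
    """
    x_a = np.asarray(counts_a, dtype=float)
    x_b = np.asarray(counts_b, dtype=float)
    post = posteriors["posterior"].to_numpy()
    slow_is_a = posteriors["slow_is_a"].to_numpy()
    n = x_a.size
    cls = np.full(n, "none", dtype=object)
    type0 = (x_a == 0) & (x_b == 0) & (consensus_a == consensus_b) & (consensus_a >= 0)
    cls[type0] = "type0"
    cls[post > cutoff] = "typeI"
    cls[np.asarray(type2_flags, dtype=bool)] = "typeII"
    is_t1 = cls == "typeI"
    slow = np.where(slow_is_a, clade_a, clade_b)
    fast = np.where(slow_is_a, clade_b, clade_a)
    return pd.DataFrame(
        {
            "column": np.arange(1, n + 1),
            "clade_a": clade_a,
            "clade_b": clade_b,
            "site_class": cls,
            "posterior": post,
            "slow_clade": np.where(is_t1, slow, ""),
            "fast_clade": np.where(is_t1, fast, ""),
        }
    )


@dataclass
class CladeData:
    """Everything the pairwise divergence scan needs about one clade."""

    clade: str
    counts: np.ndarray  # corrected per-column counts
    tree_length: float
    root_states: np.ndarray  # int codes at the clade tree root
    consensus: np.ndarray  # per-column consensus residue codes
    raw_counts: np.ndarray = field(default=None)


def pairwise_theta_table(
    clade_data: dict[str, CladeData],
    conservation_ceiling: float = 0.5,
) -> pd.DataFrame:
    """θ_I above the diagonal, θ_II below, for every clade pair.

    Failed type I fits leave NaN in the corresponding upper-triangle cell.
    """
    clades = sorted(clade_data)
    if len(clades) < 2:
        raise InputError("pairwise theta table needs at least two clades")
    table = pd.DataFrame(np.nan, index=clades, columns=clades)
    for i, a in enumerate(clades):
        for b in clades[i + 1 :]:
            da, db = clade_data[a], clade_data[b]
            try:
                fit = fit_type_I(da.counts, db.counts, da.tree_length, db.tree_length)
                table.loc[a, b] = fit.theta
            except InputError:
                pass
            _, t2 = classify_type_II(
                da.root_states, db.root_states, da.counts, db.counts,
                conservation_ceiling=conservation_ceiling,
            )
            table.loc[b, a] = t2.theta
    return table
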