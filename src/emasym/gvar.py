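"""Sparse graphical vector autoregression (GVAR) for EMA symptom networks.

The model for a participant's within-person standardized symptom vector
x_t is a lag-1 VAR: x_t = B x_{t-1} + e_t, e_t ~ N(0, K^{-1}). The
temporal coefficient matrix B gives directed lagged edges (entry (i, j)
is the effect of symptom j at t-1 on symptom i at t; its diagonal holds
autocorrelations), and the innovation precision K gives the
contemporaneous network as partial correlations
pcc_ij = -K_ij / sqrt(K_ii K_jj).

Estimation is a joint L1-penalized ("multivariate LASSO") scheme that
alternates (a) a precision-weighted coordinate-descent update of B under
an elementwise L1 penalty and (b) a graphical-lasso update of K on the
current residual covariance, until the joint penalized negative
log-likelihood stabilizes. Penalty pairs are selected by the extended
Bayesian information criterion (EBIC); an edge is "present" when its
coefficient is nonzero at the selected penalties.

Lagged pairs honour the diary structure: a (t-1, t) pair is used only
when both prompts are completed and fall on the same day — lags never
span the overnight gap or a missing prompt, and nothing is imputed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from .data_model import SYMPTOMS, Cohort, ParticipantSeries

_ZERO_TOL = 1e-8


@dataclass
class LaggedDesign:
    """Within-person standardized (x_{t-1}, x_t) pairs for GVAR fitting."""

    x: np.ndarray  # (n_pairs, k) predictors at t-1
    y: np.ndarray  # (n_pairs, k) responses at t
    variables: tuple[str, ...]
    participant_ids: np.ndarray  # per-row source participant
    low_data: bool = False  # fewer usable pairs than the per-subject minimum
    dropped: tuple[str, ...] = ()  # zero-variance variables removed

    @property
    def n_pairs(self) -> int:
        return self.x.shape[0]

    @property
    def k(self) -> int:
        return self.x.shape[1]


def _series_matrix(
    series: ParticipantSeries,
    variables: tuple[str, ...],
    activity: pd.Series | None,
) -> tuple[np.ndarray, list, list[int]]:
    """Raw variable matrix over completed entries plus (day, slot) keys."""
    cols = []
    for var in variables:
        if var == "activity":
            if activity is None:
                raise ValueError("variable 'activity' requested but no activity given")
            anchors = [
                r.timestamp.replace(
                    hour=0, minute=0, second=0, microsecond=0
                )
                for r in series.records
            ]
            # preceding-window activity is indexed by the scheduled prompt time
            sched_hours = {1: 8, 2: 11, 3: 14, 4: 17, 5: 20}
            vals = []
            for r in series.records:
                anchor = r.timestamp.replace(
                    hour=sched_hours[r.prompt_slot], minute=0, second=0, microsecond=0
                )
                vals.append(float(activity.get(anchor, np.nan)))
            cols.append(np.array(vals))
        else:
            cols.append(series.values(var))
    mat = np.column_stack(cols) if cols else np.empty((0, len(variables)))
    keys = [(r.timestamp.date(), r.prompt_slot) for r in series.records]
    ok_rows = [i for i in range(mat.shape[0]) if np.all(np.isfinite(mat[i]))]
    return mat, keys, ok_rows


def build_lagged(
    series: ParticipantSeries,
    variables: tuple[str, ...] = SYMPTOMS,
    activity: pd.Series | None = None,
    min_pairs: int = 10,
    on_zero_variance: str = "drop",
) -> LaggedDesign:
    """Construct one participant's lagged design.

    Values are within-person centered and scaled to unit (sample) variance
    over that participant's completed entries before pairing. Zero-variance
    variables are dropped with a diagnostic (``on_zero_variance="drop"``,
    the individual-model behaviour) or kept as all-zero deviations
    (``"zero"``: a constant series deviates from its own mean by exactly
    zero, which keeps the participant's rows usable in pooled designs).
    Pairs are consecutive same-day completed slots only.
    """
    mat, keys, ok_rows = _series_matrix(series, tuple(variables), activity)
    mat = mat[ok_rows]
    keys = [keys[i] for i in ok_rows]

    dropped = []
    keep_idx = []
    for j, var in enumerate(variables):
        sd = np.std(mat[:, j], ddof=1) if mat.shape[0] > 1 else 0.0
        if sd <= 0 or not np.isfinite(sd):
            dropped.append(var)
        else:
            keep_idx.append(j)
    if on_zero_variance == "zero":
        z = np.zeros_like(mat)
        if mat.shape[0]:
            mean = mat.mean(axis=0)
            sd = mat.std(axis=0, ddof=1)
            nz = [j for j in keep_idx]
            z[:, nz] = (mat[:, nz] - mean[nz]) / sd[nz]
        used = tuple(variables)
        dropped = tuple(dropped)  # still reported as a diagnostic
    elif on_zero_variance == "drop":
        used = tuple(v for j, v in enumerate(variables) if j in keep_idx)
        z = mat[:, keep_idx]
        if z.size:
            z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown on_zero_variance mode {on_zero_variance!r}")

    xs, ys = [], []
    for i in range(1, len(keys)):
        d0, s0 = keys[i - 1]
        d1, s1 = keys[i]
        if d0 == d1 and s1 == s0 + 1:  # consecutive same-day completed slots
            xs.append(z[i - 1])
            ys.append(z[i])
    x = np.array(xs) if xs else np.empty((0, len(used)))
    y = np.array(ys) if ys else np.empty((0, len(used)))
    return LaggedDesign(
        x=x,
        y=y,
        variables=used,
        participant_ids=np.repeat(series.participant_id, len(xs)),
        low_data=len(xs) < min_pairs,
        dropped=tuple(dropped),
    )


def concat_designs(designs: list[LaggedDesign]) -> LaggedDesign:
    """Pool several participants' designs (all must share variables)."""
    vars0 = designs[0].variables
    if any(d.variables != vars0 for d in designs):
        raise ValueError("cannot pool designs with differing variable sets")
    return LaggedDesign(
        x=np.vstack([d.x for d in designs]),
        y=np.vstack([d.y for d in designs]),
        variables=vars0,
        participant_ids=np.concatenate([d.participant_ids for d in designs]),
    )


@dataclass
class GvarModel:
    """A fitted GVAR at one penalty pair."""

    variables: tuple[str, ...]
    beta: np.ndarray  # (k, k) temporal coefficients, row = response
    kappa: np.ndarray  # (k, k) innovation precision
    pcc: np.ndarray  # contemporaneous partial correlations, zero diagonal
    lambda_beta: float
    lambda_kappa: float
    n_pairs: int
    loglik: float
    ebic: float
    gamma: float
    converged: bool = True
    ridge_stabilized: bool = False

    @property
    def temporal_edges(self) -> set[tuple[str, str]]:
        """Directed (from, to) pairs with nonzero lag-1 coefficient."""
        v = self.variables
        return {
            (v[j], v[i])
            for i in range(len(v))
            for j in range(len(v))
            if abs(self.beta[i, j]) > _ZERO_TOL
        }

    @property
    def contemporaneous_edges(self) -> set[frozenset]:
        v = self.variables
        return {
            frozenset((v[i], v[j]))
            for i in range(len(v))
            for j in range(i + 1, len(v))
            if abs(self.pcc[i, j]) > _ZERO_TOL
        }

    @property
    def df(self) -> int:
        k = len(self.variables)
        nb = int(np.sum(np.abs(self.beta) > _ZERO_TOL))
        nk = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if abs(self.kappa[i, j]) > _ZERO_TOL
        )
        return nb + nk


def partial_correlations(kappa: np.ndarray) -> np.ndarray:
    """pcc_ij = -kappa_ij / sqrt(kappa_ii kappa_jj); zero diagonal."""
    d = np.sqrt(np.diag(kappa))
    p = -kappa / np.outer(d, d)
    np.fill_diagonal(p, 0.0)
    return p


def _beta_step_py(b, kappa, s_xx, s_xy, lam, tol, max_sweeps):
    k = b.shape[0]
    g = 2.0 * (kappa @ b @ s_xx - kappa @ s_xy.T)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for i in range(k):
            for j in range(k):
                h = 2.0 * kappa[i, i] * s_xx[j, j]
                if h <= 0:
                    continue
                v = b[i, j] - g[i, j] / h
                t = lam / h
                new = np.sign(v) * max(abs(v) - t, 0.0)
                delta = new - b[i, j]
                if delta != 0.0:
                    b[i, j] = new
                    for r in range(k):
                        g[r] += 2.0 * delta * kappa[r, i] * s_xx[j]
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
        if max_delta < tol:
            break
    return b


try:  # jit the hot loop when numba is present; the Python path is identical
    from numba import njit

    _beta_step_jit = njit(cache=True)(_beta_step_py)
except ImportError:  # pragma: no cover
    _beta_step_jit = None


def _beta_step(
    b: np.ndarray,
    kappa: np.ndarray,
    s_xx: np.ndarray,
    s_xy: np.ndarray,
    lam: float,
    tol: float = 1e-7,
    max_sweeps: int = 200,
) -> np.ndarray:
    """Coordinate descent for the precision-weighted L1 regression:
    minimize tr(S(B) K) + lam * sum|B| with S(B) the residual covariance.

    The smooth gradient is G = 2 (K B S_xx - K S_xy^T); coordinate (i, j)
    has curvature h = 2 K_ii (S_xx)_jj, giving the exact update
    b_ij <- soft(b_ij - g_ij / h, lam / h).
    """
    step = _beta_step_jit if _beta_step_jit is not None else _beta_step_py
    return step(
        np.ascontiguousarray(b, dtype=np.float64).copy(),
        np.ascontiguousarray(kappa, dtype=np.float64),
        np.ascontiguousarray(s_xx, dtype=np.float64),
        np.ascontiguousarray(s_xy, dtype=np.float64),
        float(lam),
        float(tol),
        int(max_sweeps),
    )


def _glasso_safe(
    s_res: np.ndarray, alpha: float, k: int
) -> tuple[np.ndarray, bool]:
    """Graphical lasso with escalating ridge stabilization for
    ill-conditioned residual covariances (small individual designs at
    tiny penalties); the final fallback is a ridge pseudo-inverse."""
    for bump in (0.0, 1e-4, 1e-2):
        s2 = s_res + bump * np.trace(s_res) / k * np.eye(k)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, kappa = graphical_lasso(s2, alpha=alpha)
            return kappa, bump > 0
        except FloatingPointError:
            continue
    return np.linalg.pinv(s_res + 1e-2 * np.trace(s_res) / k * np.eye(k)), True


def _residual_cov(
    s_yy: np.ndarray, s_xy: np.ndarray, s_xx: np.ndarray, b: np.ndarray
) -> np.ndarray:
    s = s_yy - s_xy @ b.T - b @ s_xy.T + b @ s_xx @ b.T
    return (s + s.T) / 2.0


def fit_gvar(
    design: LaggedDesign,
    lambda_beta: float,
    lambda_kappa: float,
    gamma: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 50,
    beta_init: np.ndarray | None = None,
    kappa_init: np.ndarray | None = None,
    kappa_fixed: np.ndarray | None = None,
) -> GvarModel:
    """Fit the GVAR at one penalty pair by alternating estimation.

    ``kappa_fixed`` freezes the precision (used for path diagnostics and
    oracle tests); otherwise K is re-estimated by graphical lasso on the
    current residual covariance each iteration.
    """
    n, k = design.n_pairs, design.k
    if n < k:
        raise ValueError(f"need at least k={k} lagged pairs, got {n}")
    if lambda_beta < 0 or lambda_kappa < 0:
        raise ValueError("penalties must be non-negative")
    x, y = design.x, design.y
    s_xx = x.T @ x / n
    s_xy = x.T @ y / n  # (k, k): predictors x responses
    s_yy = y.T @ y / n

    b = np.zeros((k, k)) if beta_init is None else beta_init.copy()
    if kappa_fixed is not None:
        kappa = kappa_fixed.copy()
    elif kappa_init is not None:
        kappa = kappa_init.copy()
    else:
        kappa = np.diag(1.0 / np.maximum(np.diag(s_yy), 1e-10))
    ridge_used = False
    converged = False
    prev_obj = np.inf
    for _ in range(max_iter):
        b = _beta_step(b, kappa, s_xx, s_xy, lambda_beta)
        s_res = _residual_cov(s_yy, s_xy, s_xx, b)
        ev_min = np.linalg.eigvalsh(s_res).min()
        if ev_min < 1e-10:
            s_res += (1e-6 * np.trace(s_res) / k + abs(min(ev_min, 0))) * np.eye(k)
            ridge_used = True
        if kappa_fixed is None:
            if lambda_kappa > 0:
                kappa, bumped = _glasso_safe(s_res, lambda_kappa, k)
                ridge_used = ridge_used or bumped
            else:
                kappa = np.linalg.inv(s_res)
        sign, logdet = np.linalg.slogdet(kappa)
        obj = (
            -logdet
            + np.trace(s_res @ kappa)
            + lambda_beta * np.abs(b).sum()
            + lambda_kappa * (np.abs(kappa).sum() - np.abs(np.diag(kappa)).sum())
        )
        if abs(prev_obj - obj) < tol:
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn(
            f"GVAR did not converge at (lb={lambda_beta:.4g}, lk={lambda_kappa:.4g})",
            stacklevel=2,
        )

    # clean near-zero precision entries so edge sets are well defined
    kd = np.sqrt(np.diag(kappa))
    small = np.abs(kappa) < 1e-6 * np.outer(kd, kd)
    np.fill_diagonal(small, False)
    kappa = np.where(small, 0.0, kappa)
    b = np.where(np.abs(b) < _ZERO_TOL, 0.0, b)

    s_res = _residual_cov(s_yy, s_xy, s_xx, b)
    sign, logdet = np.linalg.slogdet(kappa)
    loglik = 0.5 * n * (logdet - np.trace(s_res @ kappa) - k * np.log(2 * np.pi))
    model = GvarModel(
        variables=design.variables,
        beta=b,
        kappa=kappa,
        pcc=partial_correlations(kappa),
        lambda_beta=lambda_beta,
        lambda_kappa=lambda_kappa,
        n_pairs=n,
        loglik=loglik,
        ebic=np.nan,
        gamma=gamma,
        converged=converged,
        ridge_stabilized=ridge_used,
    )
    model.ebic = ebic_score(model)
    return model


def ebic_score(model: GvarModel) -> float:
    """EBIC = -2 loglik + df log(n) + 4 gamma df log(k)."""
    df = model.df
    return (
        -2.0 * model.loglik
        + df * np.log(model.n_pairs)
        + 4.0 * model.gamma * df * np.log(len(model.variables))
    )


def lambda_grid(
    design: LaggedDesign, n_lambda: int = 20, ratio: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced penalty grids from the data-driven lambda_max (smallest
    penalty that zeroes everything, computed with an identity-scaled
    initial precision) down to ratio * lambda_max."""
    n = design.n_pairs
    s_xy = design.x.T @ design.y / n
    s_yy = design.y.T @ design.y / n
    lb_max = 2.0 * np.max(np.abs(s_xy)) / max(np.min(np.diag(s_yy)), 1e-10)
    off = np.abs(s_yy - np.diag(np.diag(s_yy)))
    lk_max = max(np.max(off), 1e-3)
    lb = np.geomspace(lb_max, ratio * lb_max, n_lambda)
    lk = np.geomspace(lk_max, ratio * lk_max, n_lambda)
    return lb, lk


def select_ebic(
    design: LaggedDesign,
    lambda_betas: np.ndarray | None = None,
    lambda_kappas: np.ndarray | None = None,
    gamma: float = 0.5,
    n_lambda: int = 20,
) -> GvarModel:
    """Fit every penalty pair on the grid and return the EBIC minimizer;
    ties break toward larger penalties (the sparser model)."""
    if lambda_betas is None or lambda_kappas is None:
        lb, lk = lambda_grid(design, n_lambda=n_lambda)
        lambda_betas = lb if lambda_betas is None else np.asarray(lambda_betas)
        lambda_kappas = lk if lambda_kappas is None else np.asarray(lambda_kappas)
    best: GvarModel | None = None
    any_converged = False
    # iterate from largest penalties downward so equal-EBIC ties keep the
    # sparser (larger-penalty) model; warm-start B along the path
    b_warm = k_warm = None
    for lb in sorted(np.asarray(lambda_betas), reverse=True):
        for lk in sorted(np.asarray(lambda_kappas), reverse=True):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_gvar(
                    design, lb, lk, gamma=gamma, beta_init=b_warm, kappa_init=k_warm
                )
            b_warm, k_warm = model.beta, model.kappa
            any_converged = any_converged or model.converged
            if model.converged and (best is None or model.ebic < best.ebic - 1e-12):
                best = model
    if best is None:
        if not any_converged:
            raise RuntimeError("no grid point converged")
        raise RuntimeError("EBIC selection failed")
    return best


@dataclass
class NetworkSet:
    """The three-level network decomposition plus per-participant fits."""

    variables: tuple[str, ...]
    between: np.ndarray  # partial correlations of person means
    contemporaneous: np.ndarray  # pooled within-person pcc
    temporal: np.ndarray  # pooled within-person standardized lag-1 coefficients
    pooled_model: GvarModel
    individual: dict[str, GvarModel]
    skipped: dict[str, str] = field(default_factory=dict)

    def edge_list(self) -> pd.DataFrame:
        """All nonzero edges across networks in long form."""
        rows = []
        v = self.variables
        k = len(v)

        def sym_edges(mat, net, owner):
            for i in range(k):
                for j in range(i + 1, k):
                    if abs(mat[i, j]) > _ZERO_TOL:
                        rows.append((v[i], v[j], mat[i, j], net, owner))

        sym_edges(self.between, "between", "between")
        sym_edges(self.contemporaneous, "contemporaneous", "pooled")
        for i in range(k):
            for j in range(k):
                if abs(self.temporal[i, j]) > _ZERO_TOL:
                    rows.append((v[j], v[i], self.temporal[i, j], "temporal", "pooled"))
        for pid, m in self.individual.items():
            vm = m.variables
            pcc, beta = m.pcc, m.beta
            for i in range(len(vm)):
                for j in range(i + 1, len(vm)):
                    if abs(pcc[i, j]) > _ZERO_TOL:
                        rows.append((vm[i], vm[j], pcc[i, j], "contemporaneous", pid))
            for i in range(len(vm)):
                for j in range(len(vm)):
                    if abs(beta[i, j]) > _ZERO_TOL:
                        rows.append((vm[j], vm[i], beta[i, j], "temporal", pid))
        return pd.DataFrame(
            rows, columns=["from", "to", "weight", "network_type", "participant_id"]
        )

    def to_networkx(self):
        """The pooled contemporaneous network as a weighted nx.Graph."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.variables)
        k = len(self.variables)
        for i in range(k):
            for j in range(i + 1, k):
                w = self.contemporaneous[i, j]
                if abs(w) > _ZERO_TOL:
                    g.add_edge(self.variables[i], self.variables[j], weight=float(w))
        return g


def glasso_ebic(
    s: np.ndarray, n: int, gamma: float = 0.5, n_lambda: int = 20, ratio: float = 0.01
) -> np.ndarray:
    """EBIC-selected graphical-lasso precision for a covariance matrix
    (used for the between-person network of person means)."""
    k = s.shape[0]
    off = np.abs(s - np.diag(np.diag(s)))
    lmax = max(np.max(off), 1e-3)
    best_prec, best_score = None, np.inf
    for lam in np.geomspace(lmax, ratio * lmax, n_lambda):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = graphical_lasso(s, alpha=lam)
        except FloatingPointError:
            continue
        _, logdet = np.linalg.slogdet(prec)
        ll = 0.5 * n * (logdet - np.trace(s @ prec) - k * np.log(2 * np.pi))
        df = sum(
            1 for i in range(k) for j in range(i + 1, k) if abs(prec[i, j]) > 1e-6
        )
        score = -2 * ll + df * np.log(n) + 4 * gamma * df * np.log(k)
        if score < best_score - 1e-12:
            best_prec, best_score = prec, score
    if best_prec is None:
        best_prec = np.linalg.inv(s + 1e-4 * np.trace(s) / k * np.eye(k))
    kd = np.sqrt(np.diag(best_prec))
    small = np.abs(best_prec) < 1e-6 * np.outer(kd, kd)
    np.fill_diagonal(small, False)
    return np.where(small, 0.0, best_prec)


def between_network(
    cohort: Cohort, variables: tuple[str, ...] = SYMPTOMS, gamma: float = 0.5
) -> np.ndarray:
    """Partial correlations of per-participant mean VAS (graphical-lasso
    regularized, EBIC-selected)."""
    means = []
    for p in cohort:
        means.append([float(np.mean(p.values(v))) for v in variables])
    m = np.array(means)
    sd = m.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        warnings.warn("degenerate person-mean covariance; adding jitter diagnostics")
        sd = np.where(sd <= 0, 1.0, sd)
    z = (m - m.mean(axis=0)) / sd
    s = z.T @ z / len(z)
    prec = glasso_ebic(s, n=len(z), gamma=gamma)
    return partial_correlations(prec)


def pooled_networks(
    cohort: Cohort,
    variables: tuple[str, ...] = SYMPTOMS,
    activity_by_participant: dict[str, pd.Series] | None = None,
    gamma: float = 0.5,
    pooled_n_lambda: int = 20,
    individual_n_lambda: int = 10,
    min_pairs: int = 10,
    fit_individuals: bool = True,
) -> NetworkSet:
    """Between, pooled-contemporaneous, pooled-temporal and per-individual
    networks. When ``activity_by_participant`` maps participants to their
    preceding-window mean ENMO series, "activity" may be included as an
    extra network variable.
    """
    if len(cohort) < 2:
        raise ValueError("pooled networks need at least 2 participants")
    pooled_designs, indiv_designs, skipped = [], {}, {}
    for p in cohort:
        act = (activity_by_participant or {}).get(p.participant_id)
        dp = build_lagged(
            p, variables, activity=act, min_pairs=min_pairs, on_zero_variance="zero"
        )
        if dp.n_pairs > 0:
            pooled_designs.append(dp)
        di = build_lagged(p, variables, activity=act, min_pairs=min_pairs)
        if di.dropped:
            skipped[p.participant_id] = (
                f"individual model drops zero-variance variables: {di.dropped}"
            )
        indiv_designs[p.participant_id] = di

    pooled_design = concat_designs(pooled_designs)
    pooled = select_ebic(pooled_design, gamma=gamma, n_lambda=pooled_n_lambda)

    individual = {}
    if fit_individuals:
        for pid, d in indiv_designs.items():
            if d.low_data or d.k == 0:
                skipped[pid] = f"only {d.n_pairs} lagged pairs (<{min_pairs})"
                continue
            individual[pid] = select_ebic(d, gamma=gamma, n_lambda=individual_n_lambda)

    bet_vars = tuple(v for v in variables if v != "activity")
    between = between_network(cohort, bet_vars, gamma=gamma)
    if len(bet_vars) != len(variables):  # pad activity row/col with zeros
        kfull = len(variables)
        full = np.zeros((kfull, kfull))
        idx = [variables.index(v) for v in bet_vars]
        full[np.ix_(idx, idx)] = between
        between = full

    return NetworkSet(
        variables=tuple(variables),
        between=between,
        contemporaneous=pooled.pcc,
        temporal=pooled.beta,
        pooled_model=pooled,
        individual=individual,
        skipped=skipped,
    )


def autocorrelation_profile(networks: NetworkSet) -> pd.DataFrame:
    """Per-participant count of nonzero temporal-diagonal entries (lag-1
    self-effects retained by the LASSO at the selected penalties)."""
    rows = []
    for pid, m in networks.individual.items():
        diag = np.diag(m.beta)
        rows.append(
            {
                "participant_id": pid,
                "n_autocorrelations": int(np.sum(np.abs(diag) > _ZERO_TOL)),
                "max_abs_autocorrelation": float(np.max(np.abs(diag))) if len(diag) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def edge_recovery(
    model: GvarModel,
    true_beta: np.ndarray,
    true_pcc: np.ndarray,
    strong: float = 0.3,
) -> dict:
    """Support/sign recovery of a pooled fit against generator ground
    truth: sensitivity over strong true edges (|coef| >= ``strong``),
    sign agreement on detected strong edges, and false discovery over all
    detected edges versus the full true support."""
    est_b, est_p = model.beta, model.pcc
    tb, tp = np.asarray(true_beta), np.asarray(true_pcc)
    k = tb.shape[0]

    def stats_for(est, true, symmetric):
        idx = (
            [(i, j) for i in range(k) for j in range(i + 1, k)]
            if symmetric
            else [(i, j) for i in range(k) for j in range(k)]
        )
        strong_idx = [ij for ij in idx if abs(true[ij]) >= strong]
        detected = [ij for ij in idx if abs(est[ij]) > _ZERO_TOL]
        tp_strong = [ij for ij in strong_idx if abs(est[ij]) > _ZERO_TOL]
        sign_ok = [ij for ij in tp_strong if np.sign(est[ij]) == np.sign(true[ij])]
        false = [ij for ij in detected if abs(true[ij]) <= _ZERO_TOL]
        return {
            "n_strong": len(strong_idx),
            "n_detected": len(detected),
            "n_strong_detected": len(tp_strong),
            "n_sign_correct": len(sign_ok),
            "n_false": len(false),
        }

    sb = stats_for(est_b, tb, symmetric=False)
    sp = stats_for(est_p, tp, symmetric=True)
    n_strong = sb["n_strong"] + sp["n_strong"]
    n_hit = sb["n_strong_detected"] + sp["n_strong_detected"]
    n_det = sb["n_detected"] + sp["n_detected"]
    n_false = sb["n_false"] + sp["n_false"]
    return {
        "temporal": sb,
        "contemporaneous": sp,
        "sensitivity": n_hit / n_strong if n_strong else float("nan"),
        "fdr": n_false / n_det if n_det else 0.0,
        "sign_accuracy": (
            (sb["n_sign_correct"] + sp["n_sign_correct"]) / n_hit if n_hit else float("nan")
        ),
    }
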