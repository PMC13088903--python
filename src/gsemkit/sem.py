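"""Structural equation models on a genetic covariance matrix.

The modeling core of the package, organized like a statsmodels estimator: a
:class:`GsemModel` is built from a :class:`~gsemkit.ldsc.GenomicCovariance`
(the data: S and the sampling covariance V of vech(S)) plus a
:class:`SemModel` path specification; ``fit()`` minimizes the diagonally
weighted least squares discrepancy

    F(theta) = (s - sigma(theta))' diag(V)^{-1} (s - sigma(theta))

and returns a :class:`GsemResults` carrying parameter estimates, sandwich
standard errors, the residual-based model chi-square computed with the full
V, CFI, SRMR, AIC and the standardized solution.

Model structure uses the RAM parameterization: directed paths in A,
variances/covariances in S_sym, implied covariance
F (I - A)^{-1} S_sym (I - A)^{-T} F'.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import GenomicCovariance
from .utils import ConfigurationError, InputError, vech, vech_indices, vech_rows_cols

logger = logging.getLogger(__name__)

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")

# sampling variances at or below this are treated as fixed (non-stochastic)
# moments and excluded from the fit function and the chi-square
FIXED_MOMENT_VARIANCE = 1e-11


@dataclass
class PathRow:
    """One entry of the parameter table.

    op '=~': lhs is a latent, rhs an indicator (directed lhs -> rhs).
    op '~' : regression, lhs on rhs (directed rhs -> lhs).
    op '~~': variance (lhs == rhs) or covariance.
    ``constraint='unit_total'`` marks a residual variance determined by the
    requirement that the variable's total implied variance equal 1 (used by
    standardized higher-order models); it is not a free parameter.
    """

    lhs: str
    op: str
    rhs: str
    free: bool = True
    value: float | None = None  # fixed value, or start value if free
    label: str | None = None
    constraint: str | None = None

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return f"{self.lhs}{self.op}{self.rhs}"


@dataclass
class SemModel:
    """A latent-variable path model: parameter table plus variable roles."""

    rows: list[PathRow] = field(default_factory=list)

    @property
    def latents(self) -> list[str]:
        seen = []
        for r in self.rows:
            if r.op == "=~" and r.lhs not in seen:
                seen.append(r.lhs)
        # regressions onto variables already known to be latent keep them latent;
        # any '~'-lhs that is not an indicator of something is treated as observed
        return seen

    @property
    def variables(self) -> list[str]:
        out = []
        for r in self.rows:
            for v in (r.lhs, r.rhs):
                if v not in out:
                    out.append(v)
        return out

    def add(self, lhs, op, rhs, free=True, value=None, label=None, constraint=None):
        self.rows.append(PathRow(lhs, op, rhs, free, value, label, constraint))
        return self

    def has(self, lhs, op, rhs) -> bool:
        return any(
            (r.lhs == lhs and r.op == op and r.rhs == rhs)
            or (op == "~~" and r.op == "~~" and r.lhs == rhs and r.rhs == lhs)
            for r in self.rows
        )

    @property
    def n_free(self) -> int:
        labels = set()
        n = 0
        for r in self.rows:
            if not r.free:
                continue
            if r.label:
                labels.add(r.label)
            else:
                n += 1
        return n + len(labels)

    @classmethod
    def from_text(cls, text: str) -> "SemModel":
        """Parse a lavaan-style model string.

        Lines like ``F1 =~ AUD + 0.5*TUD + lab*OUD``, ``F1 ~~ F2``,
        ``F2 ~ SNP``; a numeric premultiplier fixes the parameter, an
        alphanumeric one is an equality-constraint label.
        """
        model = cls()
        for raw_line in re.split(r"[\n;]+", text):
            line = raw_line.split("#")[0].strip()
            if not line:
                continue
            for op in ("=~", "~~", "~"):
                if op in line:
                    lhs, rhs_all = line.split(op, 1)
                    lhs = lhs.strip()
                    for term in rhs_all.split("+"):
                        term = term.strip()
                        if not term:
                            continue
                        free, value, label = True, None, None
                        if "*" in term:
                            pre, term = term.split("*", 1)
                            pre, term = pre.strip(), term.strip()
                            if _NUM_RE.match(pre):
                                free, value = False, float(pre)
                            else:
                                label = pre
                        model.add(lhs, op, term, free=free, value=value, label=label)
                    break
            else:
                raise ConfigurationError(f"cannot parse model line: {raw_line!r}")
        return model

    def to_text(self) -> str:
        lines = []
        for r in self.rows:
            pre = ""
            if not r.free and r.value is not None and r.constraint is None:
                pre = f"{r.value}*"
            elif r.label:
                pre = f"{r.label}*"
            lines.append(f"{r.lhs} {r.op} {pre}{r.rhs}")
        return "\n".join(lines)


def common_factor_model(factors: dict[str, list[str]], correlated: bool = True) -> SemModel:
    """First-order measurement model: each factor loads on its indicators,
    unit factor variances, free factor correlations when ``correlated``."""
    model = SemModel()
    for f, indicators in factors.items():
        for ind in indicators:
            model.add(f, "=~", ind)
        model.add(f, "~~", f, free=False, value=1.0)
    names = list(factors)
    if correlated:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                model.add(names[i], "~~", names[j], free=True, value=0.3)
    return model


def saturated_model(names: list[str]) -> SemModel:
    model = SemModel()
    for i, a in enumerate(names):
        for b in names[i:]:
            model.add(a, "~~", b)
    return model


def independence_model(names: list[str]) -> SemModel:
    model = SemModel()
    for a in names:
        model.add(a, "~~", a)
    return model


def smooth_covariance(S: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix to the nearest matrix with eigenvalues >= eps.

    Returns the (possibly unchanged) matrix and a flag saying whether
    smoothing moved it by more than 1e-12.
    """
    S = (S + S.T) / 2.0
    w, q = np.linalg.eigh(S)
    clipped = np.maximum(w, eps)
    out = (q * clipped) @ q.T
    out = (out + out.T) / 2.0
    changed = bool(np.abs(out - S).max() > 1e-12)
    return (out if changed else S), changed


# ---------------------------------------------------------------------------
# compiled model + DWLS fitting
# ---------------------------------------------------------------------------


class GsemModel:
    """Diagonally weighted least squares SEM on (S, V).

    Parameters
    ----------
    gcov : GenomicCovariance
        Genetic covariance matrix and jackknife sampling covariance.
    model : SemModel or str
        Path specification (a lavaan-style string is parsed).

    Residual variances of observed indicators and variances of exogenous
    latents get conventional defaults when the specification leaves them
    implicit: free residuals started at 0.5 * S_ii, unit fixed latent
    variances (the standardized identification the reported solutions use).
    """

    def __init__(self, gcov: GenomicCovariance, model: SemModel | str):
        if isinstance(model, str):
            model = SemModel.from_text(model)
        self.gcov = gcov
        self.model = self._with_defaults(model, gcov)
        self._compile()
        self.s_obs = vech(gcov.S)
        self.V = gcov.V
        if not (np.isfinite(self.s_obs).all() and np.isfinite(self.V).all()):
            raise InputError("non-finite entries in S or V; check the upstream regression")
        self._check_identification()

    # -- specification plumbing ------------------------------------------------

    def _with_defaults(self, model: SemModel, gcov: GenomicCovariance) -> SemModel:
        model = SemModel(rows=[replace(r) for r in model.rows])
        latents = model.latents
        observed = [v for v in gcov.trait_names]
        for v in model.variables:
            if v not in latents and v not in observed:
                raise ConfigurationError(f"model variable {v!r} not among the data traits")
        has_parent = {r.rhs for r in model.rows if r.op == "=~"} | {
            r.lhs for r in model.rows if r.op == "~"
        }
        diag_s = np.diag(gcov.S)
        for i, v in enumerate(observed):
            if v in model.variables and not model.has(v, "~~", v):
                model.add(v, "~~", v, free=True, value=0.5 * abs(diag_s[i]))
        for f in latents:
            if not model.has(f, "~~", f):
                if f in has_parent:
                    model.add(f, "~~", f, free=True, value=0.5)
                else:
                    model.add(f, "~~", f, free=False, value=1.0)
        return model

    def _compile(self):
        model, gcov = self.model, self.gcov
        latents = model.latents
        self.observed = [v for v in gcov.trait_names if v in model.variables]
        if self.observed != gcov.trait_names:
            raise ConfigurationError(
                "model must use every data trait; subset the GenomicCovariance first"
            )
        self.var_names = self.observed + latents
        self.nv = len(self.var_names)
        self.k = len(self.observed)
        idx = {v: i for i, v in enumerate(self.var_names)}

        theta_names: list[str] = []
        theta_pos: dict[str, int] = {}
        starts: list[float] = []
        self._entries_a: list[tuple[int, int, int]] = []  # (i, j, theta) for A[i, j]
        self._entries_s: list[tuple[int, int, int]] = []
        self._fixed_a: list[tuple[int, int, float]] = []
        self._fixed_s: list[tuple[int, int, float]] = []
        self._unit_total: list[int] = []  # variables with constrained residual variance

        def register(row: PathRow, default_start: float) -> int:
            name = row.name
            if name in theta_pos:
                return theta_pos[name]
            theta_pos[name] = len(theta_names)
            theta_names.append(name)
            starts.append(row.value if row.value is not None else default_start)
            return theta_pos[name]

        for row in model.rows:
            if row.op == "=~":
                i, j = idx[row.rhs], idx[row.lhs]  # lhs (latent) -> rhs
                if row.free:
                    self._entries_a.append((i, j, register(row, 0.5)))
                else:
                    self._fixed_a.append((i, j, float(row.value)))
            elif row.op == "~":
                i, j = idx[row.lhs], idx[row.rhs]  # rhs -> lhs
                if row.free:
                    self._entries_a.append((i, j, register(row, 0.0)))
                else:
                    self._fixed_a.append((i, j, float(row.value)))
            elif row.op == "~~":
                i, j = idx[row.lhs], idx[row.rhs]
                if row.constraint == "unit_total":
                    if i != j:
                        raise ConfigurationError("unit_total applies to variances only")
                    self._unit_total.append(i)
                elif row.free:
                    start = 0.3 if i != j else 0.5
                    self._entries_s.append((i, j, register(row, start)))
                else:
                    self._fixed_s.append((i, j, float(row.value)))
            else:  # pragma: no cover
                raise ConfigurationError(f"unknown operator {row.op!r}")

        self.param_names = theta_names
        self.start_values = np.asarray(starts, dtype=float)
        self.n_free = len(theta_names)

        # unit_total residuals require every parent to be exogenous (no
        # incoming directed path), so the parent-block variance is direct
        incoming = {i for (i, _, _) in self._entries_a} | {i for (i, _, _) in self._fixed_a}
        self._ut_parents: dict[int, list[tuple[int, str]]] = {}
        for f in self._unit_total:
            parents = [
                (j, "free", t) for (i, j, t) in self._entries_a if i == f
            ] + [(j, "fixed", v) for (i, j, v) in self._fixed_a if i == f]
            for j, *_ in parents:
                if j in incoming:
                    raise ConfigurationError(
                        "unit_total residual requires exogenous parents"
                    )
            self._ut_parents[f] = parents

    def _check_identification(self):
        d = len(self.s_obs)
        if self.n_free > d:
            raise ConfigurationError(
                f"model has {self.n_free} free parameters but only {d} moments"
            )

    # -- implied moments -------------------------------------------------------

    def _matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nv = self.nv
        A = np.zeros((nv, nv))
        S = np.zeros((nv, nv))
        for i, j, v in self._fixed_a:
            A[i, j] = v
        for i, j, t in self._entries_a:
            A[i, j] = theta[t]
        for i, j, v in self._fixed_s:
            S[i, j] = S[j, i] = v
        for i, j, t in self._entries_s:
            S[i, j] = S[j, i] = theta[t]
        for f, parents in self._ut_parents.items():
            tot = 0.0
            for ja, ka, va in parents:
                a_j = theta[va] if ka == "free" else va
                for jb, kb, vb in parents:
                    a_b = theta[vb] if kb == "free" else vb
                    tot += a_j * a_b * S[ja, jb]
            S[f, f] = 1.0 - tot
        return A, S

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        """Model-implied covariance among the observed variables."""
        A, S = self._matrices(np.asarray(theta, dtype=float))
        B = np.linalg.solve(np.eye(self.nv) - A, np.eye(self.nv))
        C = B @ S @ B.T
        return C[: self.k, : self.k]

    def _sigma_parts(self, theta: np.ndarray):
        A, S = self._matrices(theta)
        B = np.linalg.solve(np.eye(self.nv) - A, np.eye(self.nv))
        C = B @ S @ B.T
        return A, S, B, C

    def _jacobian(self, theta: np.ndarray, B: np.ndarray, C: np.ndarray, S: np.ndarray) -> np.ndarray:
        """d vech(Sigma) / d theta, analytic, including unit_total chain terms."""
        k, nv = self.k, self.nv
        rows, cols = vech_rows_cols(k)
        delta = np.zeros((len(rows), self.n_free))

        for i, j, t in self._entries_a:
            m1 = np.outer(B[:k, i], C[j, :k])
            d_sig = m1 + m1.T
            # chain rule through constrained residual variances
            for f, parents in self._ut_parents.items():
                grad_sff = 0.0
                for (ja, ka, va) in parents:
                    if not (ka == "free" and va == t and f == i):
                        continue
                    for jb, kb, vb in parents:
                        a_b = theta[vb] if kb == "free" else vb
                        grad_sff += -2.0 * a_b * S[ja, jb] if ja == j else 0.0
                # parents are exogenous: a single A entry (i=f, j=parent)
                if grad_sff != 0.0:
                    d_sig = d_sig + grad_sff * np.outer(B[:k, f], B[:k, f])
            delta[:, t] += d_sig[rows, cols]

        for i, j, t in self._entries_s:
            d_sig = np.outer(B[:k, i], B[:k, j])
            if i != j:
                d_sig = d_sig + d_sig.T
            delta[:, t] += d_sig[rows, cols]
        return delta

    def _moment_mask(self) -> np.ndarray:
        return np.diag(self.V) > FIXED_MOMENT_VARIANCE

    def rows_resolved(self, params: pd.Series) -> list[PathRow]:
        """Parameter-table rows with free entries filled in from estimates."""
        theta = params.to_numpy(dtype=float)
        _, S_mat = self._matrices(theta)
        idx = {v: i for i, v in enumerate(self.var_names)}
        out = []
        for r in self.model.rows:
            if r.op == "~~" and r.constraint == "unit_total":
                out.append(replace(r, value=float(S_mat[idx[r.lhs], idx[r.lhs]])))
            elif r.free:
                out.append(replace(r, value=float(params[r.name])))
            else:
                out.append(replace(r, value=float(r.value)))
        return out

    # -- estimation ------------------------------------------------------------

    def fit(
        self,
        start: np.ndarray | None = None,
        restarts: int = 5,
        gtol: float = 1e-8,
        compute_fit_indices: bool = True,
    ) -> "GsemResults":
        """Fit by DWLS with quasi-Newton iterations and jittered restarts."""
        mask = self._moment_mask()
        s = self.s_obs[mask]
        d = np.maximum(np.diag(self.V)[mask], FIXED_MOMENT_VARIANCE)
        w = 1.0 / d
        w_scale = 1.0 / np.median(w)
        wn = w * w_scale
        rows, cols = vech_rows_cols(self.k)

        def objective(theta):
            A, S, B, C = self._sigma_parts(theta)
            sig = C[rows, cols][mask]
            r = s - sig
            delta = self._jacobian(theta, B, C, S)[mask]
            grad = -2.0 * delta.T @ (wn * r)
            return float(r @ (wn * r)), grad

        if self.n_free == 0:
            return self._finalize(np.empty(0), True, 0.0, compute_fit_indices)
        theta0 = self.start_values.copy() if start is None else np.asarray(start, dtype=float)
        rng = np.random.default_rng(0)
        best = None
        converged = False
        for attempt in range(restarts + 1):
            t0 = theta0 if attempt == 0 else theta0 + rng.normal(scale=0.1, size=len(theta0))
            res = optimize.minimize(
                objective, t0, jac=True, method="L-BFGS-B",
                options={"maxiter": 500, "gtol": gtol, "ftol": 1e-14},
            )
            if best is None or res.fun < best.fun:
                best = res
            grad_ok = np.max(np.abs(res.jac)) < max(gtol * 1e6, 1e-4 * max(1.0, abs(res.fun)))
            if res.success or grad_ok:
                converged = True
                best = res if res.fun <= best.fun else best
                break
        if not converged:
            logger.warning("GsemModel.fit: no convergence after %d restarts", restarts)
        return self._finalize(best.x, converged, float(best.fun / w_scale), compute_fit_indices)

    def fit_fast(self, start: np.ndarray | None = None, max_iter: int = 30, tol: float = 1e-10) -> "GsemResults":
        """Gauss-Newton DWLS fit for small, nearly linear problems.

        The per-SNP regressions (a handful of free paths entering the implied
        moments almost linearly) converge in 2-4 iterations; heavier
        measurement models should use :meth:`fit`.
        """
        if self.n_free == 0:
            return self._finalize(np.empty(0), True, 0.0, compute_fit_indices=False)
        mask = self._moment_mask()
        s = self.s_obs[mask]
        w = 1.0 / np.maximum(np.diag(self.V)[mask], FIXED_MOMENT_VARIANCE)
        rows, cols = vech_rows_cols(self.k)
        theta = self.start_values.copy() if start is None else np.asarray(start, dtype=float)
        converged = False
        obj = np.inf
        for _ in range(max_iter):
            A, S, B, C = self._sigma_parts(theta)
            r = s - C[rows, cols][mask]
            obj = float(r @ (w * r))
            delta = self._jacobian(theta, B, C, S)[mask]
            g = delta.T @ (w * r)
            h = delta.T @ (w[:, None] * delta)
            try:
                step = np.linalg.solve(h, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(h, g, rcond=None)[0]
            theta = theta + step
            if float(np.abs(step).max()) < 1e-8 or float(g @ step) < tol * max(obj, 1.0):
                converged = True
                break
        return self._finalize(theta, converged, obj, compute_fit_indices=False)

    def _finalize(self, theta: np.ndarray, converged: bool, objective: float,
                  compute_fit_indices: bool) -> "GsemResults":
        mask = self._moment_mask()
        w = 1.0 / np.maximum(np.diag(self.V)[mask], FIXED_MOMENT_VARIANCE)
        rows, cols = vech_rows_cols(self.k)
        A, S, B, C = self._sigma_parts(theta)
        resid_vech = self.s_obs - C[rows, cols]
        fixed_resid = np.abs(resid_vech[~mask])
        if fixed_resid.size and fixed_resid.max() > 1e-6:
            logger.warning("fixed moments not reproduced exactly (max dev %.2g)", fixed_resid.max())

        delta = self._jacobian(theta, B, C, S)[mask]
        V = self.V[np.ix_(mask, mask)]

        # sandwich covariance of theta_hat
        bread_inner = delta.T @ (w[:, None] * delta)
        flag_singular = False
        try:
            bread = np.linalg.inv(bread_inner)
        except np.linalg.LinAlgError:
            bread = np.linalg.pinv(bread_inner)
            flag_singular = True
        if not flag_singular and bread_inner.size and np.linalg.cond(bread_inner) > 1e10:
            flag_singular = True
        meat = delta.T @ (w[:, None] * V * w[None, :]) @ delta
        cov_params = bread @ meat @ bread

        # residual-based model chi-square using the full V
        r = resid_vech[mask]
        try:
            vi = np.linalg.pinv(V, rcond=1e-10, hermitian=True)
        except np.linalg.LinAlgError:
            vi = np.linalg.pinv(V + 1e-12 * np.eye(len(V)), rcond=1e-10)
        a1 = delta.T @ vi @ delta
        mid = vi - vi @ delta @ np.linalg.pinv(a1, rcond=1e-10) @ delta.T @ vi
        chi2 = float(max(r @ mid @ r, 0.0))
        df = int(mask.sum()) - self.n_free

        return GsemResults(
            model=self,
            params=pd.Series(theta, index=self.param_names),
            cov_params=cov_params,
            chi2=chi2,
            df=df,
            converged=converged,
            objective=objective,
            non_identified=flag_singular,
            _implied=C,
            _compute_fit_indices=compute_fit_indices,
        )


@dataclass
class GsemResults:
    """Fitted DWLS SEM: estimates, uncertainties, fit indices, diagnostics."""

    model: GsemModel
    params: pd.Series
    cov_params: np.ndarray
    chi2: float
    df: int
    converged: bool
    objective: float
    non_identified: bool = False
    _implied: np.ndarray = field(default=None, repr=False)
    _compute_fit_indices: bool = True
    _baseline: tuple | None = field(default=None, repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.maximum(np.diag(self.cov_params), 0.0)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def pvalue(self) -> float:
        if self.df <= 0:
            return 1.0
        return float(stats.chi2.sf(self.chi2, self.df))

    @property
    def n_free(self) -> int:
        return self.model.n_free

    @property
    def aic(self) -> float:
        return self.chi2 + 2.0 * self.n_free

    @property
    def implied(self) -> np.ndarray:
        return self._implied[: self.model.k, : self.model.k]

    @property
    def resid(self) -> np.ndarray:
        return self.model.gcov.S - self.implied

    def _baseline_fit(self) -> tuple[float, int]:
        if self._baseline is None:
            base = GsemModel(self.model.gcov, independence_model(self.model.observed))
            bres = base.fit(restarts=2, compute_fit_indices=False)
            self._baseline = (bres.chi2, bres.df)
        return self._baseline

    @property
    def cfi(self) -> float:
        chi2_b, df_b = self._baseline_fit()
        num = max(self.chi2 - self.df, 0.0)
        den = max(chi2_b - df_b, self.chi2 - self.df, 0.0)
        if den <= 0.0:
            return 1.0
        return float(np.clip(1.0 - num / den, 0.0, 1.0))

    @property
    def srmr(self) -> float:
        S = self.model.gcov.S
        sd = np.sqrt(np.abs(np.diag(S)))
        denom = np.outer(sd, sd)
        resid = (S - self.implied) / denom
        rows, cols = np.tril_indices(len(sd))
        return float(np.sqrt(np.mean(resid[rows, cols] ** 2)))

    @property
    def heywood(self) -> bool:
        """Any negative residual variance in the solution (allowed, flagged)."""
        std = self.standardized
        res = std[(std["op"] == "~~") & (std["lhs"] == std["rhs"])]
        return bool((res["estimate"] < 0).any())

    @property
    def standardized(self) -> pd.DataFrame:
        """Standardized solution over every parameter-table row."""
        C = self._implied
        v_all = np.maximum(np.diag(C), 1e-12)
        idx = {v: i for i, v in enumerate(self.model.var_names)}
        rows = []
        for r in self.model.rows_resolved(self.params):
            i, j = idx[r.lhs], idx[r.rhs]
            if r.op == "=~":
                std = r.value * np.sqrt(v_all[i] / v_all[j])
                i, j = j, i  # direction latent -> indicator
            elif r.op == "~":
                std = r.value * np.sqrt(v_all[j] / v_all[i])
            else:
                if r.lhs == r.rhs:
                    std = r.value / v_all[i]
                else:
                    std = C[i, j] / np.sqrt(v_all[i] * v_all[j]) if r.free else r.value
            rows.append(
                {"lhs": r.lhs, "op": r.op, "rhs": r.rhs, "estimate": r.value, "std": std, "free": r.free}
            )
        return pd.DataFrame(rows)

    def standardized_loading(self, factor: str, indicator: str) -> float:
        std = self.standardized
        row = std[(std["op"] == "=~") & (std["lhs"] == factor) & (std["rhs"] == indicator)]
        if len(row) == 0:
            raise KeyError(f"no loading {factor} =~ {indicator}")
        return float(row["std"].iloc[0])

    def factor_correlation(self, f1: str, f2: str) -> float:
        C = self._implied
        idx = {v: i for i, v in enumerate(self.model.var_names)}
        i, j = idx[f1], idx[f2]
        return float(C[i, j] / np.sqrt(C[i, i] * C[j, j]))

    def residual_variance(self, var: str, standardized: bool = True) -> float:
        std = self.standardized
        row = std[(std["op"] == "~~") & (std["lhs"] == var) & (std["rhs"] == var)]
        if len(row) == 0:
            raise KeyError(f"no residual variance for {var}")
        return float(row["std" if standardized else "estimate"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Genomic SEM (diagonally weighted least squares)",
            "=" * 64,
            f"traits: {', '.join(self.model.observed)}",
            f"free parameters: {self.n_free}   moments: {len(self.model.s_obs)}",
            f"chi2({self.df}) = {self.chi2:.2f}   p = {self.pvalue:.3g}",
            f"AIC = {self.aic:.2f}   CFI = {self.cfi:.3f}   SRMR = {self.srmr:.4f}",
            f"converged: {self.converged}" + ("   [non-identified region]" if self.non_identified else ""),
            "-" * 64,
            f"{'parameter':<24}{'estimate':>10}{'se':>10}{'z':>8}{'std':>8}",
        ]
        bse = self.bse
        std_map = {}
        for _, row in self.standardized.iterrows():
            std_map[f"{row['lhs']}{row['op']}{row['rhs']}"] = row["std"]
        for name in self.params.index:
            est, se = self.params[name], bse[name]
            z = est / se if se > 0 else np.nan
            std = std_map.get(name, np.nan)
            lines.append(f"{name:<24}{est:>10.4f}{se:>10.4f}{z:>8.2f}{std:>8.4f}")
        return "\n".join(lines)


def fit_cfa(gcov: GenomicCovariance, model: SemModel | str, **kwargs) -> GsemResults:
    """Convenience wrapper: build a :class:`GsemModel` and fit it."""
    return GsemModel(gcov, model).fit(**kwargs)


def compare_nested(fit_restricted: GsemResults, fit_full: GsemResults) -> dict:
    """Chi-square difference test between nested DWLS fits."""
    df_diff = fit_restricted.df - fit_full.df
    if df_diff <= 0:
        raise ConfigurationError("restricted model must have more df than the full model")
    chi2_diff = max(fit_restricted.chi2 - fit_full.chi2, 0.0)
    return {
        "chi2_diff": chi2_diff,
        "df_diff": df_diff,
        "p": float(stats.chi2.sf(chi2_diff, df_diff)) if chi2_diff > 0 else 1.0,
    }


def build_second_order(
    first_order: SemModel,
    spec: dict[str, list[str]],
    orthogonal: bool = True,
    constrain_residuals: bool = False,
) -> SemModel:
    """Layer second-order factors over the first-order factors.

    ``spec`` maps each second-order latent to the first-order factors it
    loads on (a first-order factor may appear under several second-order
    latents).  First-order factor correlations are removed; second-order
    latents get unit variance and are mutually orthogonal unless
    ``orthogonal=False``.  With ``constrain_residuals=True`` the first-order
    factors' residual variances are determined by the unit-total-variance
    constraint rather than freed — the standardized bookkeeping in which the
    free parameters are exactly the second-order loadings.  In that
    configuration individual loadings of a factor serving two second-order
    latents may be identified only up to scale; the fit flags this.
    """
    fo_factors = first_order.latents
    for so, members in spec.items():
        if len(members) < 2:
            raise ConfigurationError(f"second-order factor {so} needs >= 2 first-order factors")
        for mname in members:
            if mname not in fo_factors:
                raise ConfigurationError(f"{mname} is not a first-order factor")

    model = SemModel()
    for r in first_order.rows:
        drop = (
            r.op == "~~"
            and r.lhs in fo_factors
            and r.rhs in fo_factors
        )
        if not drop:
            model.rows.append(replace(r))
    for so, members in spec.items():
        for mname in members:
            model.add(so, "=~", mname)
        model.add(so, "~~", so, free=False, value=1.0)
    so_names = list(spec)
    for i in range(len(so_names)):
        for j in range(i + 1, len(so_names)):
            if orthogonal:
                model.add(so_names[i], "~~", so_names[j], free=False, value=0.0)
            else:
                model.add(so_names[i], "~~", so_names[j], free=True, value=0.3)
    covered = {mname for members in spec.values() for mname in members}
    for f in covered:
        if constrain_residuals:
            model.add(f, "~~", f, free=False, constraint="unit_total")
        else:
            model.add(f, "~~", f, free=True, value=0.5)
    return model


# ---------------------------------------------------------------------------
# exploratory factor analysis
# ---------------------------------------------------------------------------


@dataclass
class EfaResult:
    loadings: pd.DataFrame  # rotated pattern matrix
    factor_corr: np.ndarray
    eigenvalues: np.ndarray
    prop_var: np.ndarray
    uniquenesses: np.ndarray
    heywood: bool
    n_factors: int
    salient_threshold: float = 0.35

    @property
    def salient(self) -> pd.DataFrame:
        return self.loadings.abs() >= self.salient_threshold


def suggest_n_factors(S: np.ndarray) -> int:
    """Kaiser rule on the smoothed correlation matrix: eigenvalues > 1."""
    R = _to_correlation(S)
    return int((np.linalg.eigvalsh(R) > 1.0).sum())


def _to_correlation(S: np.ndarray) -> np.ndarray:
    S, _ = smooth_covariance(S, eps=1e-6)
    d = np.sqrt(np.abs(np.diag(S)))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    R, _ = smooth_covariance(R, eps=1e-6)
    d2 = np.sqrt(np.diag(R))
    R = R / np.outer(d2, d2)
    return R


def _ml_factor(R: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood factor extraction: returns (loadings, uniquenesses)."""
    p = R.shape[0]

    def neg_ll(log_u):
        u = np.exp(log_u)
        su = 1.0 / np.sqrt(u)
        m = (su[:, None] * R) * su[None, :]
        w = np.sort(np.linalg.eigvalsh(m))[::-1]
        tail = w[q:]
        tail = np.maximum(tail, 1e-8)
        return float(np.sum(tail - np.log(tail) - 1.0))

    # start from 1 - squared multiple correlation, the classic initial guess
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    x0 = np.log(np.clip(1.0 - smc, 6e-3, 1.0))
    res = optimize.minimize(
        neg_ll, x0, method="L-BFGS-B", bounds=[(np.log(5e-3), np.log(1.0))] * p,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    u = np.exp(res.x)
    su = 1.0 / np.sqrt(u)
    m = (su[:, None] * R) * su[None, :]
    w, vec = np.linalg.eigh(m)
    order = np.argsort(w)[::-1][:q]
    lam = vec[:, order] * np.sqrt(np.maximum(w[order] - 1.0, 0.0))[None, :]
    loadings = np.sqrt(u)[:, None] * lam
    return loadings, u


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    p, q = L.shape
    if q < 2:
        return L
    rot = np.eye(q)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ rot
        u, s, vt = np.linalg.svd(L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p))
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ rot


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation from a varimax start; returns (pattern, Phi)."""
    X = _varimax(L)
    if X.shape[1] < 2 or np.abs(X).max() < 1e-8:
        return X, np.eye(X.shape[1])
    # column-normalize by communalities (Kaiser), as in the classic procedure
    h = np.sqrt((X**2).sum(axis=1))
    Xn = X / np.maximum(h, 1e-12)[:, None]
    target = np.abs(Xn) ** power * np.sign(Xn)
    U, *_ = np.linalg.lstsq(Xn, target, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]
    pattern = X @ U
    phi = np.linalg.inv(U.T @ U)
    d_phi = np.sqrt(np.diag(phi))
    phi = phi / np.outer(d_phi, d_phi)
    return pattern, phi


def efa(
    gcov: GenomicCovariance | np.ndarray,
    n_factors: int,
    trait_names: list[str] | None = None,
    salient_threshold: float = 0.35,
) -> EfaResult:
    """Maximum-likelihood exploratory factor analysis with promax rotation.

    Runs on the smoothed genetic correlation matrix; with one factor the
    unrotated solution is returned.  Heywood cases (communality reaching 1)
    are flagged, not fatal.
    """
    if isinstance(gcov, GenomicCovariance):
        S = gcov.S
        trait_names = trait_names or gcov.trait_names
    else:
        S = np.asarray(gcov, dtype=float)
        trait_names = trait_names or [f"V{i + 1}" for i in range(S.shape[0])]
    p = S.shape[0]
    if not (0 < n_factors < p):
        raise ConfigurationError(f"n_factors must be in 1..{p - 1}, got {n_factors}")
    R = _to_correlation(S)
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    L, u = _ml_factor(R, n_factors)
    heywood = bool(np.any(u <= 5.5e-3))
    if heywood:
        logger.warning("efa: Heywood case (communality ~ 1) flagged")
    if n_factors > 1:
        pattern, phi = _promax(L)
    else:
        pattern, phi = L, np.eye(1)
    # column sign convention: dominant loading positive
    signs = np.sign(pattern[np.abs(pattern).argmax(axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    pattern = pattern * signs[None, :]
    phi = phi * np.outer(signs, signs)
    cols = [f"F{i + 1}" for i in range(n_factors)]
    return EfaResult(
        loadings=pd.DataFrame(pattern, index=trait_names, columns=cols),
        factor_corr=phi,
        eigenvalues=eigenvalues,
        prop_var=eigenvalues[:n_factors] / p,
        uniquenesses=u,
        heywood=heywood,
        n_factors=n_factors,
        salient_threshold=salient_threshold,
    )
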