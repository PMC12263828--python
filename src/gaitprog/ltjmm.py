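"""Latent-time joint mixed-effect model (LTJMM).

Aligns multi-outcome longitudinal trajectories on a common latent disease
timescale.  For patient ``i``, visit ``j``, outcome ``k``:

    y_ijk = beta_k' x_ij + gamma_k (t_ij + delta_i)
            + alpha0_ik + alpha1_ik t_ij + eps_ijk

where ``delta_i ~ N(0, sigma_delta^2)`` is a time shift shared across
outcomes, ``(alpha0_ik, alpha1_ik)`` are correlated per-outcome random
intercepts/slopes and ``eps_ijk ~ N(0, sigma_k^2)``.  The shift places every
patient on a common disease clock: ``t + delta_i`` is the latent disease
time, and ``alpha1_ik`` (deviation from the population slope ``gamma_k``)
is the patient's individual progression rate for outcome ``k``.

Estimation integrates all random effects analytically (the model is jointly
Gaussian), maximising the exact marginal likelihood over the fixed effects
and variance parameters with L-BFGS-B on bounded log-scales; per-patient
effects are then empirical-Bayes posterior means.  ``method="mcmc"`` samples
the same marginal posterior with emcee.  Time and covariates are centered
internally, which makes the fit exactly equivariant under a constant shift
of the observation times.

Identifiability: with a single outcome the time shift trades off against
the intercept (a warning is emitted); with K >= 2 outcomes the shared delta
is resolved by the cross-outcome covariance.  delta is re-centered to mean
zero after fitting, absorbed into the per-outcome intercepts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LTJMM", "LTJMMResults", "holdout_last_visit", "hy_alignment_check"]

_LOG_LO, _LOG_HI = -7.0, 6.0
_ZRHO_BOUND = 2.5
_JITTER = 1e-9


class FitError(RuntimeError):
    pass


@dataclass
class _Group:
    """Patients sharing an observation count, stacked for batched linalg."""

    pids: list
    y: np.ndarray        # (B, m)
    t: np.ndarray        # (B, m) centered times
    x: np.ndarray        # (B, m, p) centered covariates
    onehot: np.ndarray   # (B, m, K)
    kidx: np.ndarray     # (B, m) outcome index per row


class LTJMM:
    """Model object: long-format multi-outcome data plus a model spec.

    Parameters
    ----------
    data : DataFrame
        Long clinical table, one row per visit, with the outcome columns,
        the time column and the covariate columns.
    outcomes : list of str
        Outcome score columns (K >= 1).
    covariates : list of str
        Fixed-effect adjustment covariates.  A ``sex`` column with M/F
        values is coded as a male indicator.
    time : str
        Column holding years since diagnosis.
    gamma_fixed : dict, optional
        Map outcome -> fixed value for its latent-time slope (e.g. 0 to
        degenerate to an ordinary random-intercept/slope mixed model).
    """

    def __init__(self, data: pd.DataFrame, outcomes: list[str],
                 covariates: list[str] = ("age_at_diagnosis", "sex", "med_on"),
                 time: str = "years_since_diagnosis",
                 patient_col: str = "patient_id",
                 gamma_fixed: dict[str, float] | None = None):
        if not outcomes:
            raise ValueError("at least one outcome is required")
        missing = [c for c in list(outcomes) + list(covariates) + [time]
                   if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        self.outcomes = list(outcomes)
        self.covariates = list(covariates)
        self.time = time
        self.patient_col = patient_col
        self.gamma_fixed = dict(gamma_fixed or {})
        if len(self.outcomes) == 1 and not self.gamma_fixed:
            warnings.warn(
                "single-outcome LTJMM: the time shift and the intercept "
                "trade off; interpret delta with caution", UserWarning,
                stacklevel=2)
        self._prepare(data)

    @classmethod
    def from_cohort(cls, cohort, outcomes: list[str] | None = None,
                    **kwargs) -> "LTJMM":
        outcomes = outcomes or cohort.outcome_columns
        return cls(cohort.clinical, outcomes, **kwargs)

    # -- data preparation --------------------------------------------------

    def _encode_covariates(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in self.covariates:
            v = df[c]
            if v.dtype == object:
                v = v.astype(str).str.upper().eq("M").astype(float)
            cols.append(np.asarray(v, float))
        if not cols:
            return np.zeros((len(df), 0))
        x = np.column_stack(cols)
        for j, c in enumerate(self.covariates):
            if np.nanstd(x[:, j]) == 0:
                raise FitError(f"covariate {c!r} is constant "
                               "(singular design)")
        return x

    def _prepare(self, data: pd.DataFrame) -> None:
        df = data.copy()
        x_all = self._encode_covariates(df)
        keep = ~np.isnan(x_all).any(axis=1) & df[self.time].notna().to_numpy()
        self.n_dropped_rows = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        x_all = x_all[keep]

        # rounding makes the centering constant transform exactly under a
        # constant time shift, so such shifts reproduce the identical
        # optimisation problem (exact equivariance)
        self.t_center = round(float(df[self.time].mean()), 3)
        self.x_center = np.round(x_all.mean(axis=0), 3) if x_all.size \
            else np.zeros(0)
        # rounding the centered design at 1e-9 (far below data precision)
        # makes a constant time shift reproduce a bit-identical problem
        tC = np.round(df[self.time].to_numpy(float) - self.t_center, 9)
        xC = np.round(x_all - self.x_center, 9)

        K = len(self.outcomes)
        rows_y, rows_t, rows_x, rows_k, rows_pid = [], [], [], [], []
        for k, out in enumerate(self.outcomes):
            mask = df[out].notna().to_numpy()
            rows_y.append(df.loc[mask, out].to_numpy(float))
            rows_t.append(tC[mask])
            rows_x.append(xC[mask])
            rows_k.append(np.full(mask.sum(), k))
            rows_pid.append(df.loc[mask, self.patient_col].to_numpy())
        y = np.concatenate(rows_y)
        t = np.concatenate(rows_t)
        x = np.vstack(rows_x)
        kidx = np.concatenate(rows_k).astype(int)
        pid = np.concatenate(rows_pid)

        order = np.lexsort((t, kidx, pid))
        y, t, x, kidx, pid = y[order], t[order], x[order], kidx[order], pid[order]

        self.patients = list(pd.unique(pid))
        by_m: dict[int, list] = {}
        idx = pd.Series(np.arange(len(pid))).groupby(pid, sort=False).groups
        for p in self.patients:
            ii = np.asarray(idx[p])
            by_m.setdefault(len(ii), []).append((p, ii))
        groups = []
        for m, members in sorted(by_m.items()):
            pids = [p for p, _ in members]
            sel = np.stack([ii for _, ii in members])
            oh = np.eye(K)[kidx[sel]]
            groups.append(_Group(pids=pids, y=y[sel], t=t[sel], x=x[sel],
                                 onehot=oh, kidx=kidx[sel]))
        self._groups = groups
        self.n_obs = len(y)
        self.K, self.p = K, x.shape[1]
        self.df_long = pd.DataFrame({
            self.patient_col: pid, "_t": t + self.t_center, "_k": kidx,
            "_y": y})

    # -- parameter packing -------------------------------------------------
    # theta = [log sigma_delta] + per outcome
    #         [b0, beta_1..p, (gamma), log sigma, log tau0, log tau1, z_rho]

    def _n_per_outcome(self, out: str) -> int:
        return self.p + 5 + (0 if out in self.gamma_fixed else 1)

    def _unpack(self, theta: np.ndarray):
        K, p = self.K, self.p
        log_sd = theta[0]
        b0 = np.empty(K)
        beta = np.empty((K, p))
        gamma = np.empty(K)
        sig = np.empty(K)
        tau0 = np.empty(K)
        tau1 = np.empty(K)
        rho = np.empty(K)
        pos = 1
        for k, out in enumerate(self.outcomes):
            b0[k] = theta[pos]; pos += 1
            beta[k] = theta[pos:pos + p]; pos += p
            if out in self.gamma_fixed:
                gamma[k] = self.gamma_fixed[out]
            else:
                gamma[k] = theta[pos]; pos += 1
            sig[k] = np.exp(theta[pos]); pos += 1
            tau0[k] = np.exp(theta[pos]); pos += 1
            tau1[k] = np.exp(theta[pos]); pos += 1
            rho[k] = np.tanh(theta[pos]); pos += 1
        return np.exp(log_sd), b0, beta, gamma, sig, tau0, tau1, rho

    def _G(self, sd, tau0, tau1, rho) -> np.ndarray:
        # random-effect layout: [delta, alpha0_1..K, alpha1_1..K]
        K = self.K
        G = np.zeros((1 + 2 * K, 1 + 2 * K))
        G[0, 0] = sd ** 2
        for k in range(K):
            i, j = 1 + k, 1 + K + k
            G[i, i] = tau0[k] ** 2
            G[j, j] = tau1[k] ** 2
            G[i, j] = G[j, i] = rho[k] * tau0[k] * tau1[k]
        return G

    def _group_VZr(self, g: _Group, params):
        sd, b0, beta, gamma, sig, tau0, tau1, rho = params
        mean = (b0[g.kidx] + np.einsum("bmp,bmp->bm", g.x, beta[g.kidx])
                + gamma[g.kidx] * g.t)
        r = g.y - mean
        Z = np.concatenate([
            gamma[g.kidx][..., None],
            g.onehot,
            g.onehot * g.t[..., None]], axis=2)
        G = self._G(sd, tau0, tau1, rho)
        V = np.einsum("bmi,ij,bnj->bmn", Z, G, Z)
        m = g.y.shape[1]
        V[:, np.arange(m), np.arange(m)] += sig[g.kidx] ** 2 + _JITTER
        return V, Z, G, r

    def loglike(self, theta: np.ndarray) -> float:
        """Exact marginal log-likelihood (random effects integrated out)."""
        params = self._unpack(theta)
        total = 0.0
        for g in self._groups:
            V, _, _, r = self._group_VZr(g, params)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return -np.inf
            w = np.linalg.solve(L, r[..., None])[..., 0]
            m = r.shape[1]
            total += float(
                -0.5 * (m * np.log(2 * np.pi) * r.shape[0]
                        + 2 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
                        + (w ** 2).sum()))
        return total

    def _negloglike(self, theta: np.ndarray) -> float:
        ll = self.loglike(theta)
        if not np.isfinite(ll):
            return 1e12
        # weak shrinkage on the intercept-slope correlations (MAP-style
        # regularisation; keeps rho off the +/-1 boundary)
        zrho = self._zrho_values(theta)
        return -ll + 0.5 * float(np.sum(zrho ** 2)) / 9.0

    def _zrho_values(self, theta: np.ndarray) -> np.ndarray:
        out, pos = [], 1
        for k, o in enumerate(self.outcomes):
            pos += 1 + self.p + (0 if o in self.gamma_fixed else 1) + 3
            out.append(theta[pos]); pos += 1
        return np.asarray(out)

    def _start(self, sigma_delta_init: float) -> tuple[np.ndarray, list]:
        theta = [np.log(max(sigma_delta_init, 1e-3))]
        bounds = [(np.log(1e-3), 3.5)]
        xs = np.concatenate([g.x.reshape(g.x.shape[0] * g.x.shape[1], self.p)
                             for g in self._groups])
        ks = np.concatenate([g.kidx.ravel() for g in self._groups])
        ys = np.concatenate([g.y.ravel() for g in self._groups])
        ts = np.concatenate([g.t.ravel() for g in self._groups])
        for k, out in enumerate(self.outcomes):
            # per-outcome OLS on [1, x, t] for starting values
            sel = ks == k
            A = np.column_stack([np.ones(sel.sum()), xs[sel], ts[sel]])
            coef, *_ = np.linalg.lstsq(A, ys[sel], rcond=None)
            resid = ys[sel] - A @ coef
            s = max(float(resid.std()), 1e-2)
            tspread = max(float(ts[sel].std()), 0.25)
            theta.append(coef[0]); bounds.append((None, None))
            for b in coef[1:1 + self.p]:
                theta.append(b); bounds.append((None, None))
            if out not in self.gamma_fixed:
                theta.append(coef[-1]); bounds.append((None, None))
            theta += [np.log(0.7 * s), np.log(0.7 * s),
                      np.log(max(0.3 * s / tspread, 2e-3)), 0.0]
            bounds += [(_LOG_LO, _LOG_HI)] * 3 + [(-_ZRHO_BOUND, _ZRHO_BOUND)]
        return np.asarray(theta, float), bounds

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "map", maxiter: int = 500, tol: float = 1e-8,
            gtol: float = 1e-9, seed: int = 0, sigma_delta_init: float = 1.0,
            compute_se: bool = False, mcmc_steps: int = 600,
            mcmc_burn: int = 300) -> "LTJMMResults":
        """Fit by marginal maximum likelihood (``map``) or MCMC (``mcmc``).

        Deterministic for fixed seed.  ``tol`` is the relative objective
        change used for convergence (L-BFGS-B ``ftol``); ``gtol`` the
        projected-gradient stopping threshold.
        """
        theta0, bounds = self._start(sigma_delta_init)
        trace: list[float] = [self._negloglike(theta0)]
        res = optimize.minimize(
            self._negloglike, theta0, method="L-BFGS-B", bounds=bounds,
            callback=lambda xk: trace.append(self._negloglike(xk)),
            options={"maxiter": maxiter, "ftol": tol, "gtol": gtol,
                     "maxfun": 200000})
        theta = res.x
        converged = bool(res.success)
        if method == "mcmc":
            theta = self._run_mcmc(theta, bounds, seed, mcmc_steps, mcmc_burn)
            converged = True
        elif method != "map":
            raise ValueError(f"method must be 'map' or 'mcmc', got {method!r}")

        se = self._laplace_se(theta) if compute_se else None
        return LTJMMResults(self, theta, converged=converged,
                            objective_trace=trace, loglik=self.loglike(theta),
                            n_iter=int(res.nit), theta_se=se)

    def _run_mcmc(self, theta_map, bounds, seed, steps, burn) -> np.ndarray:
        import emcee

        ndim = len(theta_map)
        lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
        hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])

        def logprob(th):
            if np.any(th < lo) or np.any(th > hi):
                return -np.inf
            return -self._negloglike(th)

        nwalkers = max(2 * ndim + 2, 32)
        rng = np.random.default_rng(seed)
        p0 = theta_map + 1e-3 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logprob)
        state = emcee.State(p0, random_state=np.random.RandomState(seed))
        sampler.run_mcmc(state, steps, progress=False)
        chain = sampler.get_chain(discard=burn, flat=True)
        return chain.mean(axis=0)

    def _laplace_se(self, theta: np.ndarray) -> np.ndarray:
        """Standard errors from a finite-difference Hessian at the optimum."""
        n = len(theta)
        h = 1e-4 * np.maximum(1.0, np.abs(theta))
        H = np.zeros((n, n))
        f0 = self._negloglike(theta)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                fpp = self._negloglike(theta + ei + ej)
                fpm = self._negloglike(theta + ei - ej)
                fmp = self._negloglike(theta - ei + ej)
                fmm = self._negloglike(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(n, np.nan)
        return se


class LTJMMResults:
    """Fitted LTJMM: estimates, per-patient effects, diagnostics."""

    def __init__(self, model: LTJMM, theta: np.ndarray, converged: bool,
                 objective_trace: list[float], loglik: float, n_iter: int,
                 theta_se: np.ndarray | None = None):
        self.model = model
        self.theta = np.asarray(theta, float)
        self.converged = converged
        self.objective_trace = list(objective_trace)
        self.loglik = float(loglik)
        self.n_iter = n_iter
        self.theta_se = theta_se
        self._extract()

    # -- parameter extraction ---------------------------------------------

    def _extract(self) -> None:
        m = self.model
        sd, b0, beta, gamma, sig, tau0, tau1, rho = m._unpack(self.theta)
        params = (sd, b0, beta, gamma, sig, tau0, tau1, rho)
        K = m.K

        # empirical-Bayes posterior means/sds of (delta, alpha0', alpha1)
        delta, dvar = {}, {}
        a0p = {o: {} for o in m.outcomes}
        a1 = {o: {} for o in m.outcomes}
        a1var = {o: {} for o in m.outcomes}
        for g in m._groups:
            V, Z, G, r = m._group_VZr(g, params)
            L = np.linalg.cholesky(V)
            Wr = np.linalg.solve(L, r[..., None])[..., 0]
            WZ = np.linalg.solve(L, Z)
            u = np.einsum("ij,bmj,bm->bi", G, WZ, Wr)
            A = np.einsum("ij,bmj,bmn,nl->bil", G, WZ, WZ, G)
            pcov = G[None] - A
            for b, pid in enumerate(g.pids):
                delta[pid] = u[b, 0]
                dvar[pid] = pcov[b, 0, 0]
                for k, out in enumerate(m.outcomes):
                    a0p[out][pid] = u[b, 1 + k]
                    a1[out][pid] = u[b, 1 + K + k]
                    a1var[out][pid] = pcov[b, 1 + K + k, 1 + K + k]

        order = m.patients
        dbar = float(np.mean([delta[p] for p in order]))
        # soft-centering: subtract the mean shift, absorb into intercepts
        self.delta = pd.Series({p: delta[p] - dbar for p in order},
                               name="delta_hat").loc[order]
        self.delta_se = pd.Series({p: np.sqrt(max(dvar[p], 0.0))
                                   for p in order}).loc[order]
        b0 = b0 + gamma * dbar

        c = m.t_center
        self.sigma_delta = sd
        self.params = {}
        for k, out in enumerate(m.outcomes):
            # random-effect covariance back-transformed to the t = 0 origin
            # (internally the intercept refers to the centered time)
            var0 = (tau0[k] ** 2 - 2 * c * rho[k] * tau0[k] * tau1[k]
                    + c ** 2 * tau1[k] ** 2)
            cov01 = rho[k] * tau0[k] * tau1[k] - c * tau1[k] ** 2
            t0_ext = float(np.sqrt(max(var0, 0.0)))
            rho_ext = float(cov01 / (t0_ext * tau1[k])) \
                if t0_ext > 0 and tau1[k] > 0 else 0.0
            self.params[out] = {
                "intercept": float(b0[k] - gamma[k] * c
                                   - beta[k] @ m.x_center),
                "beta": dict(zip(m.covariates, beta[k].tolist())),
                "gamma": float(gamma[k]),
                "sigma": float(sig[k]),
                "tau0": t0_ext,
                "tau1": float(tau1[k]),
                "rho": rho_ext,
            }
        self.alpha1 = pd.DataFrame(
            {out: pd.Series(a1[out]).loc[order] for out in m.outcomes})
        self.alpha1_se = pd.DataFrame(
            {out: pd.Series({p: np.sqrt(max(a1var[out][p], 0.0))
                             for p in order}).loc[order]
             for out in m.outcomes})
        # external alpha0 = alpha0' - alpha1 * t_center
        self.alpha0 = pd.DataFrame(
            {out: pd.Series(a0p[out]).loc[order]
             - self.alpha1[out] * c for out in m.outcomes})
        self._b0_internal = b0
        self._beta = beta
        self._gamma = gamma

    # -- public accessors --------------------------------------------------

    def latent_time(self, patient_id, t):
        """Latent disease time ``t + delta_hat`` (vectorised over both)."""
        pid = np.atleast_1d(np.asarray(patient_id, object))
        tt = np.broadcast_to(np.atleast_1d(np.asarray(t, float)), pid.shape) \
            if np.size(t) == 1 else np.atleast_1d(np.asarray(t, float))
        unknown = [p for p in pid if p not in self.delta.index]
        if unknown:
            raise KeyError(f"unknown patient(s): {unknown}")
        out = tt + self.delta.loc[pid].to_numpy()
        return float(out[0]) if np.isscalar(patient_id) and np.size(t) == 1 \
            else out

    def random_slope(self, outcome: str, patient_id=None):
        """Per-patient deviation alpha1 from the population slope gamma."""
        if outcome not in self.alpha1.columns:
            raise KeyError(f"unknown outcome {outcome!r}")
        s = self.alpha1[outcome]
        return s if patient_id is None else float(s.loc[patient_id])

    def progression_rate(self, outcome: str, total: bool = False):
        """alpha1 (deviation) or gamma + alpha1 (absolute rate/yr)."""
        s = self.random_slope(outcome)
        return s + self.params[outcome]["gamma"] if total else s

    def predict_outcome(self, patient_id, outcome: str, t,
                        covariates: dict | None = None):
        """Plug the patient's effects into the model equation."""
        if outcome not in self.params:
            raise KeyError(f"unknown outcome {outcome!r}")
        if patient_id not in self.delta.index:
            raise KeyError(f"unknown patient {patient_id!r}")
        p = self.params[outcome]
        covariates = covariates or {}
        fixed = p["intercept"]
        for name, b in p["beta"].items():
            if name not in covariates:
                raise KeyError(f"missing covariate value for {name!r}")
            v = covariates[name]
            if isinstance(v, str):
                v = 1.0 if v.upper() == "M" else 0.0
            fixed += b * float(v)
        t = np.asarray(t, float)
        y = (fixed + p["gamma"] * (t + self.delta.loc[patient_id])
             + self.alpha0.loc[patient_id, outcome]
             + self.alpha1.loc[patient_id, outcome] * t)
        return float(y) if y.ndim == 0 else y

    def fittedvalues(self) -> pd.Series:
        m = self.model
        sd, b0, beta, gamma, sig, tau0, tau1, rho = m._unpack(self.theta)
        d = m.df_long
        pid = d[m.patient_col].to_numpy()
        k = d["_k"].to_numpy()
        t = d["_t"].to_numpy()
        out = np.empty(len(d))
        for i in range(len(d)):
            o = m.outcomes[k[i]]
            out[i] = (self.params[o]["intercept"]
                      + gamma[k[i]] * (t[i] + self.delta[pid[i]])
                      + self.alpha0.loc[pid[i], o]
                      + self.alpha1.loc[pid[i], o] * t[i])
        return pd.Series(out, index=d.index)

    def summary(self) -> str:
        lines = ["Latent-time joint mixed-effect model",
                 "=" * 52,
                 f"patients: {len(self.delta)}   observations: "
                 f"{self.model.n_obs}   outcomes: {self.model.K}",
                 f"log-likelihood: {self.loglik:.3f}   converged: "
                 f"{self.converged}   iterations: {self.n_iter}",
                 f"sigma_delta (time-shift sd, yr): {self.sigma_delta:.4f}",
                 ""]
        rows = []
        for out, p in self.params.items():
            rows.append({"outcome": out, "gamma (units/yr)": p["gamma"],
                         "intercept": p["intercept"], "sigma": p["sigma"],
                         "tau0": p["tau0"], "tau1": p["tau1"],
                         "rho": p["rho"],
                         **{f"beta[{c}]": v for c, v in p["beta"].items()}})
        lines.append(pd.DataFrame(rows).set_index("outcome")
                     .to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "outcomes": self.model.outcomes,
            "covariates": self.model.covariates,
            "sigma_delta": self.sigma_delta,
            "params": self.params,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def effects_to_csv(self, path) -> None:
        df = pd.DataFrame({"patient_id": self.delta.index,
                           "delta_hat": self.delta.to_numpy()})
        for out in self.model.outcomes:
            df[f"alpha0_{out}"] = self.alpha0[out].to_numpy()
            df[f"alpha1_{out}"] = self.alpha1[out].to_numpy()
        df.to_csv(path, index=False)


# -- validation procedures --------------------------------------------------

def holdout_last_visit(cohort, outcomes: list[str] | None = None,
                       covariates=("age_at_diagnosis", "sex", "med_on"),
                       **fit_kwargs) -> dict:
    """Last-visit holdout validation of the LTJMM.

    Excludes each patient's last observed visit per outcome, refits once on
    the reduced data, predicts the dropped values from the refitted
    patient-specific effects, and returns the Pearson correlation between
    real and predicted values per outcome (with a Fisher 95% CI) plus the
    pooled correlation (mean over outcomes).
    """
    outcomes = outcomes or cohort.outcome_columns
    clin = cohort.clinical.sort_values(
        ["patient_id", "visit_date"]).reset_index(drop=True)
    counts = clin.groupby("patient_id")[list(outcomes)].count()
    ok = counts.index[(counts >= 3).all(axis=1)]
    if len(ok) < 3:
        raise FitError("holdout requires >= 3 patients with >= 3 visits "
                       "per outcome")
    clin = clin[clin["patient_id"].isin(ok)].reset_index(drop=True)

    reduced = clin.copy()
    held: dict[str, list] = {o: [] for o in outcomes}
    for out in outcomes:
        obs = clin[clin[out].notna()]
        last = obs.groupby("patient_id").tail(1)
        reduced.loc[last.index, out] = np.nan
        held[out] = last
    model = LTJMM(reduced, outcomes, covariates=list(covariates))
    res = model.fit(**fit_kwargs)

    report = {"per_outcome": {}, "pooled": np.nan}
    rhos = []
    for out in outcomes:
        rows = held[out]
        pred, real = [], []
        for _, r in rows.iterrows():
            if r["patient_id"] not in res.delta.index:
                continue
            cov = {c: r[c] for c in covariates}
            pred.append(res.predict_outcome(
                r["patient_id"], out, r["years_since_diagnosis"], cov))
            real.append(r[out])
        pred, real = np.asarray(pred), np.asarray(real)
        pr = stats.pearsonr(real, pred)
        ci = pr.confidence_interval(0.95)
        report["per_outcome"][out] = {
            "rho": float(pr.statistic), "ci_low": float(ci.low),
            "ci_high": float(ci.high), "n": int(len(real))}
        rhos.append(pr.statistic)
    report["pooled"] = float(np.mean(rhos))
    report["results"] = res
    return report


def hy_alignment_check(results: LTJMMResults, cohort) -> dict:
    """Check that latent time orders visits consistently with H&Y stages.

    Returns the visit-level Spearman correlation between latent disease
    time and the Hoehn & Yahr stage plus a table of mean latent time per
    stage.
    """
    clin = cohort.clinical
    sub = clin[clin["hy_stage"].notna()
               & clin["patient_id"].isin(results.delta.index)]
    if sub["hy_stage"].nunique() < 2:
        raise ValueError("all H&Y stages identical; correlation undefined")
    latent = sub["years_since_diagnosis"].to_numpy() + \
        results.delta.loc[sub["patient_id"]].to_numpy()
    rho = stats.spearmanr(latent, sub["hy_stage"].to_numpy()).statistic
    table = (pd.DataFrame({"hy_stage": sub["hy_stage"].to_numpy(),
                           "latent_time": latent})
             .groupby("hy_stage")["latent_time"].agg(["mean", "count"]))
    return {"spearman": float(rho), "stage_table": table}
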