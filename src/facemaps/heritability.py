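"""Classical-twin variance-components estimation by maximum likelihood.

The phenotypic variance of a trait measured on MZ and DZ twin pairs is
decomposed into additive-genetic (A), common-environment (C) and
unique-environment (E) parts.  Under the standard assumptions (equal
environments, no dominance, no assortative mating) the bivariate-normal
covariance structure of a pair is

    var       = a^2 + c^2 + e^2          (both twins, both zygosities)
    cov(MZ)   = a^2 + c^2
    cov(DZ)   = a^2 / 2 + c^2

with nonnegative path coefficients a, c, e.  Narrow-sense heritability is
h^2 = a^2 / (a^2 + c^2 + e^2).  The model ladder ACE -> AE -> E drops one
component at a time; the E component (measurement error plus unshared
environment) is always retained.  Model choice is by AIC, and overall fit
is judged with a likelihood-ratio test against a saturated model that puts
no structure on the per-zygosity means and covariances.

The API follows the statsmodels convention: ``TwinSEM`` is the model
object, ``TwinSEM(...).fit()`` returns a ``TwinSEMResults`` carrying the
estimates, standard errors, log-likelihood, AIC and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinPairData",
    "TwinSEM",
    "TwinSEMResults",
    "ModelSelection",
    "goodness_of_fit",
    "select_model",
    "ae_vs_e_test",
    "mass_univariate",
    "heritability_map",
    "power_simulation",
]

_LOG2PI = math.log(2.0 * math.pi)
_STRUCTURED = ("ACE", "AE", "E")


# ----------------------------------------------------------------------
# data container


class TwinPairData:
    """Validated twin-pair table.

    Expected columns: ``pair_id, zygosity, value_twin1, value_twin2`` and,
    optionally, ``age_twin1, age_twin2``.  Zygosity must be ``MZ`` or
    ``DZ``.
    """

    REQUIRED = ("pair_id", "zygosity", "value_twin1", "value_twin2")

    def __init__(self, table: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"pair table lacks column {col!r}")
        zcol = table.columns.get_loc("zygosity")
        for row, z in enumerate(table["zygosity"]):
            if z not in ("MZ", "DZ"):
                raise ValueError(
                    f"row {row}, column {zcol} ('zygosity'): invalid token {z!r}"
                    " (expected 'MZ' or 'DZ')")
        vals = table[["value_twin1", "value_twin2"]].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("trait values must be finite")
        if table["pair_id"].duplicated().any():
            raise ValueError("pair_id values must be unique")
        self.table = table.reset_index(drop=True)
        is_mz = (self.table["zygosity"] == "MZ").to_numpy()
        self.mz = vals[is_mz]
        self.dz = vals[~is_mz]
        if {"age_twin1", "age_twin2"}.issubset(table.columns):
            ages = self.table[["age_twin1", "age_twin2"]].to_numpy(dtype=float)
            self.mz_age = ages[is_mz]
            self.dz_age = ages[~is_mz]
        else:
            self.mz_age = self.dz_age = None

    @classmethod
    def from_csv(cls, path) -> "TwinPairData":
        return cls(pd.read_csv(path))

    @property
    def n_mz(self) -> int:
        return len(self.mz)

    @property
    def n_dz(self) -> int:
        return len(self.dz)


# ----------------------------------------------------------------------
# likelihood helpers


def _bivariate_ll(x: np.ndarray, mu: np.ndarray, var: float, cov: float) -> float:
    """Sum of bivariate-normal log-densities with exchangeable covariance."""
    det = var * var - cov * cov
    if det <= 0 or var <= 0:
        return -np.inf
    r = x - mu
    q = (var * (r[:, 0] ** 2 + r[:, 1] ** 2) - 2 * cov * r[:, 0] * r[:, 1]) / det
    n = len(x)
    return -n * _LOG2PI - 0.5 * n * math.log(det) - 0.5 * float(q.sum())


def _sat_group_ll(x, ages, mu1, mu2, l11, l21, l22, beta):
    mu = np.array([mu1, mu2])
    if ages is not None:
        m = mu + beta * ages
    else:
        m = np.broadcast_to(mu, x.shape)
    v1 = l11 * l11
    cv = l11 * l21
    v2 = l21 * l21 + l22 * l22
    det = v1 * v2 - cv * cv
    if det <= 0:
        return -np.inf
    r = x - m
    q = (v2 * r[:, 0] ** 2 + v1 * r[:, 1] ** 2 - 2 * cv * r[:, 0] * r[:, 1]) / det
    n = len(x)
    return -n * _LOG2PI - 0.5 * n * math.log(det) - 0.5 * float(q.sum())


# ----------------------------------------------------------------------
# results object


@dataclass
class TwinSEMResults:
    """Fitted twin variance-components model.

    ``params`` holds path coefficients on the trait scale (a, c, e), the
    mean ``mu`` and, when the model includes the covariate, the age slope
    ``beta_age``.  ``bse`` are standard errors from the inverse numerical
    Hessian (NaN at a boundary); ``h2_se`` uses the delta method.
    """

    model: str
    params: dict
    llf: float
    n_params: int
    nobs_pairs: int
    use_age: bool
    bse: dict = field(default_factory=dict)
    h2_se: float = float("nan")
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def h2(self) -> float:
        if self.model == "SAT":
            raise ValueError("the saturated model has no heritability")
        a = self.params.get("a", 0.0)
        c = self.params.get("c", 0.0)
        e = self.params["e"]
        tot = a * a + c * c + e * e
        return a * a / tot if tot > 0 else 0.0

    def summary(self) -> str:
        lines = [
            f"Twin variance-components model ({self.model})",
            "=" * 46,
            f"pairs: {self.nobs_pairs}    age covariate: {self.use_age}",
            f"log-likelihood: {self.llf:.4f}    AIC: {self.aic:.4f}",
            f"free parameters: {self.n_params}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            lines.append(f"{k:<10}{v:>12.5f}{se:>12.5f}")
        if self.model != "SAT":
            lines.append("-" * 46)
            lines.append(f"h2 = {self.h2:.4f}  (SE {self.h2_se:.4f})")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# model object


class TwinSEM:
    """Twin structural-equation model for one quantitative trait.

    Parameters
    ----------
    data : TwinPairData or DataFrame
        Pair table (see TwinPairData for the column contract).
    model : {"ACE", "AE", "E", "SAT"}
    use_age : bool
        Include a shared linear age effect in the mean model (requires age
        columns).
    """

    def __init__(self, data, model: str = "ACE", use_age: bool = False):
        if not isinstance(data, TwinPairData):
            data = TwinPairData(data)
        if model not in _STRUCTURED + ("SAT",):
            raise ValueError(f"unknown model {model!r}")
        if data.n_mz < 2 or data.n_dz < 2:
            raise ValueError("need at least 2 pairs of each zygosity")
        if use_age and data.mz_age is None:
            raise ValueError("use_age requires age_twin1/age_twin2 columns")
        self.data = data
        self.model = model
        self.use_age = use_age
        self._all = np.concatenate([data.mz.ravel(), data.dz.ravel()])
        if use_age:
            self._all_age = np.concatenate([data.mz_age.ravel(),
                                            data.dz_age.ravel()])
        self._scale = float(self._all.std()) or 1.0

    # -- likelihood ----------------------------------------------------

    def _structured_ll(self, mu, beta, A, C, E):
        var = A + C + E
        data = self.data
        if self.use_age:
            mu_mz = mu + beta * data.mz_age
            mu_dz = mu + beta * data.dz_age
        else:
            mu_mz = np.full_like(data.mz, mu)
            mu_dz = np.full_like(data.dz, mu)
        return (_bivariate_ll(data.mz, mu_mz, var, A + C)
                + _bivariate_ll(data.dz, mu_dz, var, 0.5 * A + C))

    def loglike(self, params: dict) -> float:
        """Log-likelihood at a parameter dict (path-coefficient scale)."""
        if self.model == "SAT":
            beta = params.get("beta_age", 0.0)
            return (_sat_group_ll(self.data.mz, self.data.mz_age if self.use_age else None,
                                  params["mu1_mz"], params["mu2_mz"],
                                  params["l11_mz"], params["l21_mz"], params["l22_mz"], beta)
                    + _sat_group_ll(self.data.dz, self.data.dz_age if self.use_age else None,
                                    params["mu1_dz"], params["mu2_dz"],
                                    params["l11_dz"], params["l21_dz"], params["l22_dz"], beta))
        a = params.get("a", 0.0)
        c = params.get("c", 0.0)
        e = params["e"]
        return self._structured_ll(params["mu"], params.get("beta_age", 0.0),
                                   a * a, c * c, e * e)

    # -- fitting -------------------------------------------------------

    def fit(self, n_starts: int = 5, seed: int = 0,
            compute_se: bool = True) -> TwinSEMResults:
        if self.model == "SAT":
            return self._fit_saturated(compute_se)
        return self._fit_structured(n_starts, seed, compute_se)

    def _moment_start(self):
        data = self.data
        v = float(self._all.var())
        cmz = float(np.cov(data.mz.T)[0, 1]) if data.n_mz > 1 else 0.0
        cdz = float(np.cov(data.dz.T)[0, 1]) if data.n_dz > 1 else 0.0
        A = max(2.0 * (cmz - cdz), 0.0)
        C = max(2.0 * cdz - cmz, 0.0)
        E = max(v - A - C, 1e-3 * v if v > 0 else 1e-6)
        return v, A, C, E

    def _fit_structured(self, n_starts, seed, compute_se):
        data = self.data
        use_age = self.use_age
        v, A0, C0, E0 = self._moment_start()
        mu0 = float(self._all.mean())
        beta0 = 0.0
        if use_age:
            X = np.c_[np.ones_like(self._all_age), self._all_age]
            coef = np.linalg.lstsq(X, self._all, rcond=None)[0]
            mu0, beta0 = float(coef[0]), float(coef[1])
        floor = 1e-10 * max(v, 1e-12)

        has_a = self.model in ("ACE", "AE")
        has_c = self.model == "ACE"

        def unpack(theta):
            i = 0
            mu = theta[i]; i += 1
            beta = 0.0
            if use_age:
                beta = theta[i]; i += 1
            A = theta[i] if has_a else 0.0
            i += has_a
            C = theta[i] if has_c else 0.0
            i += has_c
            E = theta[i]
            return mu, beta, A, C, E

        def negll(theta):
            ll = self._structured_ll(*unpack(theta))
            return -ll if np.isfinite(ll) else 1e30

        bounds = [(None, None)] + ([(None, None)] if use_age else [])
        bounds += [(0.0, None)] * (has_a + has_c) + [(floor, None)]

        rng = np.random.default_rng(seed)
        starts = []
        base = [mu0] + ([beta0] if use_age else [])
        if has_a and has_c:
            starts.append(base + [A0, C0, E0])
        elif has_a:
            starts.append(base + [A0 + C0, E0])
        else:
            starts.append(base + [max(v, floor)])
        for _ in range(n_starts - 1):
            jitter = [mu0 + self._scale * rng.normal() * 0.3]
            if use_age:
                jitter.append(beta0 * (1 + 0.3 * rng.normal()))
            shares = rng.dirichlet(np.ones(3)) * max(v, floor)
            if has_a and has_c:
                jitter += [shares[0], shares[1], max(shares[2], floor)]
            elif has_a:
                jitter += [shares[0] + shares[1], max(shares[2], floor)]
            else:
                jitter += [max(v * (1 + 0.5 * rng.normal()) ** 2, floor)]
            starts.append(jitter)

        best = None
        for x0 in starts:
            res = optimize.minimize(negll, np.asarray(x0, dtype=float),
                                    method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        mu, beta, A, C, E = unpack(best.x)
        params = {"a": math.sqrt(A)} if has_a else {}
        if has_c:
            params["c"] = math.sqrt(C)
        params["e"] = math.sqrt(E)
        params["mu"] = mu
        if use_age:
            params["beta_age"] = beta
        n_par = 1 + use_age + 1 + has_a + has_c  # mu (+beta), E, A?, C?
        result = TwinSEMResults(
            model=self.model, params=params, llf=float(-best.fun),
            n_params=n_par, nobs_pairs=data.n_mz + data.n_dz,
            use_age=use_age, converged=bool(best.success))
        if compute_se:
            self._standard_errors(result)
        return result

    def _fit_saturated(self, compute_se):
        data = self.data
        params = {}
        llf = 0.0
        if not self.use_age:
            for tag, x in (("mz", data.mz), ("dz", data.dz)):
                mu = x.mean(axis=0)
                r = x - mu
                S = r.T @ r / len(x)   # ML covariance
                L = np.linalg.cholesky(S + 1e-12 * np.eye(2) * S.trace())
                params[f"mu1_{tag}"] = float(mu[0])
                params[f"mu2_{tag}"] = float(mu[1])
                params[f"l11_{tag}"] = float(L[0, 0])
                params[f"l21_{tag}"] = float(L[1, 0])
                params[f"l22_{tag}"] = float(L[1, 1])
            llf = self.loglike(params)
            converged = True
        else:
            # shared age slope couples the groups: optimize numerically from
            # the age-free closed form
            def build(theta):
                names = ["mu1_mz", "mu2_mz", "l11_mz", "l21_mz", "l22_mz",
                         "mu1_dz", "mu2_dz", "l11_dz", "l21_dz", "l22_dz",
                         "beta_age"]
                return dict(zip(names, theta))

            def negll(theta):
                ll = self.loglike(build(theta))
                return -ll if np.isfinite(ll) else 1e30

            x0 = []
            for tag, x, ages in (("mz", data.mz, data.mz_age),
                                 ("dz", data.dz, data.dz_age)):
                X = np.c_[np.ones(2 * len(x)), ages.ravel()]
                bet = np.linalg.lstsq(X, x.ravel(), rcond=None)[0]
                resid = (x.ravel() - X @ bet).reshape(-1, 2)
                S = resid.T @ resid / len(x)
                L = np.linalg.cholesky(S + 1e-12 * np.eye(2) * S.trace())
                x0 += [bet[0], bet[0], L[0, 0], L[1, 0], L[1, 1]]
            x0.append(0.0)
            res = optimize.minimize(negll, np.asarray(x0), method="L-BFGS-B")
            params = build(res.x)
            llf = float(-res.fun)
            converged = bool(res.success)
        n_par = 10 + (1 if self.use_age else 0)
        result = TwinSEMResults(
            model="SAT", params=params, llf=float(llf), n_params=n_par,
            nobs_pairs=data.n_mz + data.n_dz, use_age=self.use_age,
            converged=converged if self.use_age else True)
        if compute_se:
            self._standard_errors(result)
        return result

    # -- uncertainty ---------------------------------------------------

    def _standard_errors(self, result: TwinSEMResults):
        """Inverse-numerical-Hessian standard errors on the reported
        parameter scale; delta-method SE for h2."""
        names = list(result.params)
        x0 = np.array([result.params[k] for k in names], dtype=float)
        step = np.maximum(np.abs(x0), self._scale * 0.1) * 1e-4

        def f(x):
            return self.loglike(dict(zip(names, x)))

        k = len(x0)
        H = np.zeros((k, k))
        f0 = f(x0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = step[i]
                ej = np.zeros(k); ej[j] = step[j]
                fij = f(x0 + ei + ej)
                fi = f(x0 + ei)
                fj = f(x0 + ej)
                H[i, j] = H[j, i] = (fij - fi - fj + f0) / (step[i] * step[j])
        try:
            cov = np.linalg.inv(-H)
            if np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
            se = np.sqrt(np.diag(cov))
            result.bse = dict(zip(names, se))
            if result.model in _STRUCTURED:
                idx = {n: i for i, n in enumerate(names)}
                a = result.params.get("a", 0.0)
                c = result.params.get("c", 0.0)
                e = result.params["e"]
                tot = a * a + c * c + e * e
                grad = np.zeros(k)
                if "a" in idx:
                    grad[idx["a"]] = 2 * a * (tot - a * a) / tot**2
                if "c" in idx:
                    grad[idx["c"]] = -2 * c * a * a / tot**2
                grad[idx["e"]] = -2 * e * a * a / tot**2
                result.h2_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            result.bse = {n: float("nan") for n in names}
            result.h2_se = float("nan")


# ----------------------------------------------------------------------
# inference helpers


def goodness_of_fit(structured: TwinSEMResults, saturated: TwinSEMResults):
    """Likelihood-ratio test of a structured model against the saturated
    one.  Returns (statistic, df, p_value)."""
    stat = 2.0 * (saturated.llf - structured.llf)
    if stat < -1e-6:
        raise ValueError(
            f"saturated log-likelihood below structured ({stat:.3g}):"
            " optimizer failure")
    stat = max(stat, 0.0)
    df = saturated.n_params - structured.n_params
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return stat, df, p


def ae_vs_e_test(data, use_age: bool = False, seed: int = 0,
                 n_starts: int = 2):
    """LRT of AE against E (is heritability zero?).

    The additive variance sits on the boundary of its space under the null,
    so the statistic follows the 50:50 mixture of chi2(0) and chi2(1); both
    the boundary-corrected and the naive chi2(1) p-values are returned.

    Returns ``(stat, p_boundary, p_naive, fit_ae, fit_e)``.
    """
    if not isinstance(data, TwinPairData):
        data = TwinPairData(data)
    fit_ae = TwinSEM(data, "AE", use_age).fit(n_starts=n_starts, seed=seed,
                                              compute_se=False)
    fit_e = TwinSEM(data, "E", use_age).fit(n_starts=1, seed=seed,
                                            compute_se=False)
    stat = max(2.0 * (fit_ae.llf - fit_e.llf), 0.0)
    if stat < 1e-8:  # boundary solution up to optimizer noise
        stat = 0.0
    p_naive = float(stats.chi2.sf(stat, 1))
    p_boundary = 1.0 if stat <= 0 else 0.5 * p_naive
    return stat, p_boundary, p_naive, fit_ae, fit_e


@dataclass
class ModelSelection:
    """Outcome of the ACE -> AE -> E ladder on one trait."""

    best: TwinSEMResults
    fits: dict
    saturated: TwinSEMResults
    gof_stat: float
    gof_df: int
    gof_p: float

    def summary(self) -> str:
        lines = ["model   k      logLik         AIC"]
        for name in _STRUCTURED:
            f = self.fits[name]
            mark = " *" if name == self.best.model else ""
            lines.append(f"{name:<6}{f.n_params:>3}{f.llf:>12.3f}{f.aic:>12.3f}{mark}")
        lines.append(f"goodness of fit vs saturated: chi2({self.gof_df}) ="
                     f" {self.gof_stat:.3f}, p = {self.gof_p:.4f}")
        return "\n".join(lines)


def select_model(data, use_age: bool = False, seed: int = 0,
                 n_starts: int = 3, compute_se: bool = True) -> ModelSelection:
    """Fit ACE, AE and E; pick the minimum-AIC model (ties favor fewer
    parameters) and test it against the saturated model."""
    if not isinstance(data, TwinPairData):
        data = TwinPairData(data)
    fits = {}
    for name in _STRUCTURED:
        fits[name] = TwinSEM(data, name, use_age).fit(
            n_starts=n_starts, seed=seed, compute_se=compute_se)
    # ties -> fewer parameters: scan in increasing-complexity order
    best = None
    for name in ("E", "AE", "ACE"):
        f = fits[name]
        if best is None or f.aic < best.aic - 1e-9:
            best = f
    sat = TwinSEM(data, "SAT", use_age).fit(compute_se=False)
    stat, df, p = goodness_of_fit(best, sat)
    return ModelSelection(best=best, fits=fits, saturated=sat,
                          gof_stat=stat, gof_df=df, gof_p=p)


# ----------------------------------------------------------------------
# batch analysis and maps


def _pair_tables(trait_matrix: pd.DataFrame, pairs: pd.DataFrame):
    for col in ("pair_id", "zygosity", "subject1", "subject2"):
        if col not in pairs.columns:
            raise ValueError(f"pair table lacks column {col!r}")
    zcol = pairs.columns.get_loc("zygosity")
    for row, z in enumerate(pairs["zygosity"]):
        if z not in ("MZ", "DZ"):
            raise ValueError(
                f"row {row}, column {zcol} ('zygosity'): invalid token {z!r}"
                " (expected 'MZ' or 'DZ')")
    missing = ((set(pairs["subject1"]) | set(pairs["subject2"]))
               - set(trait_matrix.index))
    if missing:
        raise ValueError(f"pair table references unknown subjects: {missing}")
    has_age = {"age1", "age2"}.issubset(pairs.columns)
    base = {
        "pair_id": pairs["pair_id"].to_numpy(),
        "zygosity": pairs["zygosity"].to_numpy(),
    }
    if has_age:
        base["age_twin1"] = pairs["age1"].to_numpy(dtype=float)
        base["age_twin2"] = pairs["age2"].to_numpy(dtype=float)
    i1 = trait_matrix.index.get_indexer(pairs["subject1"])
    i2 = trait_matrix.index.get_indexer(pairs["subject2"])
    return base, i1, i2


def mass_univariate(trait_matrix: pd.DataFrame, pairs: pd.DataFrame,
                    use_age: bool = False, seed: int = 0,
                    n_starts: int = 2) -> pd.DataFrame:
    """Independent model selection for every trait column.

    ``trait_matrix`` is subjects x traits (index = subject ids);
    ``pairs`` has columns ``pair_id, zygosity, subject1, subject2`` and,
    when ``use_age``, ``age1, age2``.  Traits whose optimization fails are
    flagged in the ``status`` column rather than dropped.
    """
    base, i1, i2 = _pair_tables(trait_matrix, pairs)
    rows = []
    values = trait_matrix.to_numpy(dtype=float)
    for col_idx, trait in enumerate(trait_matrix.columns):
        tab = dict(base)
        tab["value_twin1"] = values[i1, col_idx]
        tab["value_twin2"] = values[i2, col_idx]
        row = {"trait": trait}
        try:
            sel = select_model(pd.DataFrame(tab), use_age=use_age, seed=seed,
                               n_starts=n_starts, compute_se=True)
            best = sel.best
            row.update({
                "model": best.model,
                "h2": best.h2,
                "h2_se": best.h2_se,
                "a": best.params.get("a", 0.0),
                "c": best.params.get("c", 0.0),
                "e": best.params["e"],
                "llf": best.llf,
                "aic": best.aic,
                "gof_stat": sel.gof_stat,
                "gof_p": sel.gof_p,
                "status": "ok" if best.converged else "no_convergence",
            })
        except (ValueError, np.linalg.LinAlgError) as exc:
            row.update({"model": None, "h2": np.nan, "status": f"failed: {exc}"})
        rows.append(row)
    return pd.DataFrame(rows)


def heritability_map(h2_values, mesh, landmark_positions, *,
                     gof_p=None, models=None, gof_threshold: float = 0.05,
                     mask_failing: bool = False, path=None, csv_path=None):
    """Per-landmark heritability painted onto a mesh.

    Each mesh vertex takes the h2 of its nearest landmark; landmarks whose
    goodness-of-fit p-value is below ``gof_threshold`` can be masked
    (rendered neutral).  Optionally writes a colored PLY (``path``) and a
    CSV ``landmark_id,h2,gof_p,model`` (``csv_path``).  Returns the
    per-vertex scalar array.
    """
    from scipy.spatial import cKDTree

    from .mesh import write_mesh

    h2 = np.asarray(h2_values, dtype=float)
    if np.nanmin(h2) < -1e-9 or np.nanmax(h2) > 1 + 1e-9:
        raise ValueError("h2 values must lie in [0, 1]")
    pos = np.asarray(landmark_positions, dtype=float)
    if len(pos) != len(h2):
        raise ValueError("one position per h2 value required")
    shown = h2.copy()
    if mask_failing and gof_p is not None:
        shown = np.where(np.asarray(gof_p) < gof_threshold, np.nan, shown)
    _, nearest = cKDTree(pos).query(mesh.vertices)
    scalars = shown[nearest]
    if path is not None:
        write_mesh(mesh, path, fmt="ply", vertex_scalars=scalars)
    if csv_path is not None:
        pd.DataFrame({
            "landmark_id": np.arange(len(h2)),
            "h2": h2,
            "gof_p": gof_p if gof_p is not None else np.nan,
            "model": models if models is not None else "",
        }).to_csv(csv_path, index=False)
    return scalars


# ----------------------------------------------------------------------
# power


def power_simulation(n_mz: int, n_dz: int, h2_true: float, c2_true: float = 0.0,
                     n_replicates: int = 1000, alpha_level: float = 0.05,
                     seed: int = 0):
    """Monte-Carlo power of the zero-heritability (AE vs E) test.

    Each replicate simulates a twin cohort under the ACE covariance
    structure with additive share ``h2_true`` and common-environment share
    ``c2_true``, fits AE and E by maximum likelihood and rejects when the
    boundary-corrected 1-df LRT p-value is below ``alpha_level``.

    Returns a dict with the rejection ``rate``, its binomial ``se`` and the
    replicate count.
    """
    from .synthetic import simulate_twin_traits

    if n_mz < 2 or n_dz < 2 or h2_true + c2_true > 1 + 1e-12:
        raise ValueError("invalid design")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(n_replicates)]
    rejections = 0
    for s in child_seeds:
        table = simulate_twin_traits(n_mz, n_dz, h2_true, c2_true,
                                     1.0 - h2_true - c2_true, seed=s)
        _, p_boundary, _, _, _ = ae_vs_e_test(table, seed=s)
        rejections += p_boundary < alpha_level
    rate = rejections / n_replicates
    se = math.sqrt(rate * (1 - rate) / n_replicates)
    return {"rate": rate, "se": se, "n_replicates": n_replicates,
            "n_rejections": rejections}
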