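"""Negative-binomial mixed models of florivory counts.

Two analyses compare flower foraging between dichromats and trichromats:

* the *scan model* — flower-foraging scans per individual per study cycle,
  with the log of total scans as offset and crossed random intercepts for
  individual and cycle;
* the *FLPV model* — total visits to small flower patches per individual,
  with the log of group observation hours as offset and a random intercept
  for social group.

Counts are NB2 (variance ``mu + mu^2/theta``) with a log link.  The marginal
likelihood over Gaussian random intercepts is maximised with a Laplace
approximation; standard errors come from the observed information, z from
``estimate/SE`` and p from the two-sided normal approximation.

No installed Python package fits this model family, so the Laplace machinery
is implemented here; its likelihood is validated against adaptive quadrature
and against Poisson/NB regression limits in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from scipy.special import digamma, gammaln, ndtr

from .exceptions import ConvergenceError, DataError

log = logging.getLogger(__name__)

#: Flower species producing small, quickly depleted crops.  Only visits to
#: these count in the small-patch FLPV analysis.
SMALL_PATCH_SPECIES = (
    "Bromelia pinguin",
    "Bromelia plumerii",
    "Bauhinia ungulata",
    "Callistemon viminalis",
    "Centrosema macrocarpum",
    "Cordia guanacastensis",
    "Malvaviscus arboreus",
    "Pithecoctineum crucigerum",
    "Stemmedenia obovata",
    "Tabebuia ochracea",
    "Vachellia collinsii",
)


def normalize_species(name) -> str:
    """Case/whitespace normalisation used before matching species names."""
    return " ".join(str(name).strip().lower().split())


_SMALL_PATCH_NORM = {normalize_species(s) for s in SMALL_PATCH_SPECIES}


def phenotype_class_of(name) -> str:
    """``"trichromat"`` for two-allele labels like ``"532/561"``, else dichromat."""
    return "trichromat" if "/" in str(name) else "dichromat"


# ---------------------------------------------------------------------------
# data preparation


def small_patch_filter(records: pd.DataFrame, species_list=None, roster=None):
    """Restrict FLPV records to small-patch species and count per individual.

    Parameters
    ----------
    records : DataFrame
        One row per individual per flower-patch visit with columns
        ``individual_id`` and ``species`` (``group`` is carried through if
        present).
    species_list : iterable of str, optional
        Defaults to the 11 small-patch flower species.
    roster : DataFrame, optional
        With ``individual_id``; individuals absent from the filtered records
        are retained with count 0.

    Returns a DataFrame ``individual_id, n_flpv`` whose ``attrs`` record the
    retained/excluded visit counts and any unknown species encountered.
    """
    if species_list is None:
        allowed = _SMALL_PATCH_NORM
        known = _SMALL_PATCH_NORM
    else:
        allowed = {normalize_species(s) for s in species_list}
        known = allowed
    rec = records.copy()
    if "individual_id" not in rec.columns or "species" not in rec.columns:
        raise DataError("FLPV records need individual_id and species columns")
    rec["_sp"] = rec["species"].map(normalize_species)
    keep = rec["_sp"].isin(allowed)
    unknown = sorted(set(rec.loc[~keep, "_sp"]) - known)
    if unknown:
        log.info("small_patch_filter: %d visits to non-listed species excluded (%s)",
                 int((~keep).sum()), ", ".join(unknown[:5]))
    counts = (
        rec.loc[keep]
        .groupby("individual_id")
        .size()
        .rename("n_flpv")
        .reset_index()
    )
    if roster is not None:
        counts = (
            roster[["individual_id"]]
            .drop_duplicates()
            .merge(counts, on="individual_id", how="left")
            .fillna({"n_flpv": 0})
        )
    counts["n_flpv"] = counts["n_flpv"].astype(int)
    counts.attrs["n_retained_visits"] = int(keep.sum())
    counts.attrs["n_excluded_visits"] = int((~keep).sum())
    counts.attrs["excluded_species"] = unknown
    counts.attrs["n_species_retained"] = int(rec.loc[keep, "_sp"].nunique())
    return counts


def filter_eligible(scans: pd.DataFrame, min_cycles: int = 7) -> pd.DataFrame:
    """Keep individuals observed in at least ``min_cycles`` study cycles."""
    n_cycles = scans.groupby("individual_id")["cycle_id"].nunique()
    ok = n_cycles[n_cycles >= min_cycles].index
    out = scans[scans["individual_id"].isin(ok)].copy()
    out.attrs["n_individuals"] = int(len(ok))
    out.attrs["n_dropped"] = int(n_cycles.size - len(ok))
    return out


# ---------------------------------------------------------------------------
# the Laplace NB mixed model


def _nb2_loglike(y, eta, theta):
    mu = np.exp(eta)
    return np.sum(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
        + theta * np.log(theta) + y * eta - (y + theta) * np.log(mu + theta)
    )


def _nb2_u_w(y, eta, theta):
    """First derivative and (negated) second derivative of the NB2 log
    likelihood with respect to the linear predictor."""
    mu = np.exp(eta)
    u = y - (y + theta) * mu / (mu + theta)
    w = (y + theta) * theta * mu / (mu + theta) ** 2
    return u, w


@dataclass
class GLMMFit:
    """Fixed effects, dispersion and random-intercept estimates of one fit."""

    params: pd.Series
    bse: pd.Series
    theta: float
    re_sd: dict
    llf: float
    n_obs: int
    converged: bool
    boundary: dict
    message: str = ""
    random_effects: dict = field(default_factory=dict)
    optimizer_trace: object = None

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return 2.0 * (1.0 - pd.Series(ndtr(np.abs(self.zvalues)),
                                      index=self.params.index))

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "z": self.zvalues.to_dict(),
            "p": self.pvalues.to_dict(),
            "theta": self.theta,
            "re_sd": self.re_sd,
            "llf": self.llf,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
        }

    def summary(self) -> str:
        lines = [f"NB2 GLMM fit  (n={self.n_obs}, llf={self.llf:.3f}, "
                 f"theta={self.theta:.4g}, converged={self.converged})"]
        lines.append(f"{'term':<22}{'estimate':>10}{'SE':>10}{'z':>8}{'p':>9}")
        for k in self.params.index:
            lines.append(
                f"{k:<22}{self.params[k]:>10.4f}{self.bse[k]:>10.4f}"
                f"{self.zvalues[k]:>8.3f}{self.pvalues[k]:>9.4f}"
            )
        for name, sd in self.re_sd.items():
            flag = "  (boundary)" if self.boundary.get(name) else ""
            lines.append(f"random intercept {name}: sd = {sd:.4f}{flag}")
        return "\n".join(lines)


class NegativeBinomialGLMM:
    """NB2 mixed model with Gaussian random intercepts, fitted by Laplace ML.

    Parameters
    ----------
    y : array of int
        Non-negative counts.
    X : DataFrame or 2-D array
        Fixed-effect design matrix (include the intercept column).
    offset : array, optional
        Log exposure added to the linear predictor with coefficient 1.
    groups : dict of str -> array, optional
        Random-intercept grouping factors (crossed if more than one), each
        an array of level labels aligned with ``y``.
    """

    SIGMA_LOG_BOUNDS = (-8.0, 4.0)
    THETA_LOG_BOUNDS = (-4.0, 16.0)

    def __init__(self, y, X, offset=None, groups=None, exog_names=None):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise DataError("counts must be non-negative integers")
        if isinstance(X, pd.DataFrame):
            self.exog_names = list(X.columns)
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.exog_names = exog_names or [f"x{j}" for j in range(self.X.shape[1])]
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise DataError("X must be n x p aligned with y")
        self.offset = (
            np.zeros_like(self.y) if offset is None else np.asarray(offset, float)
        )
        if not np.all(np.isfinite(self.offset)):
            raise DataError("offset must be finite (log of a positive exposure)")
        self.group_names: list = []
        self.codes: list = []
        self.levels: list = []
        for name, vals in (groups or {}).items():
            vals = pd.Series(vals)
            if vals.size != self.y.size:
                raise DataError(f"grouping factor {name!r} misaligned with y")
            if vals.nunique() == 0:
                raise DataError(f"grouping factor {name!r} is empty")
            codes, levels = pd.factorize(vals, sort=True)
            self.group_names.append(name)
            self.codes.append(codes)
            self.levels.append(list(levels))
        self.q_per = [len(lv) for lv in self.levels]
        self.q = int(sum(self.q_per))
        self._offsets_b = np.concatenate([[0], np.cumsum(self.q_per)]).astype(int)
        self._b_cache = np.zeros(self.q)

    # -- latent-field machinery -----------------------------------------
    def _eta(self, beta, b):
        eta = self.X @ beta + self.offset
        for k, codes in enumerate(self.codes):
            bk = b[self._offsets_b[k]:self._offsets_b[k + 1]]
            eta = eta + bk[codes]
        return eta

    def _d_inv(self, sigmas):
        d = np.empty(self.q)
        for k in range(len(self.codes)):
            d[self._offsets_b[k]:self._offsets_b[k + 1]] = 1.0 / sigmas[k] ** 2
        return d

    def _zt(self, v):
        """Z^T v : accumulate observation vector into latent coordinates."""
        out = np.empty(self.q)
        for k, codes in enumerate(self.codes):
            out[self._offsets_b[k]:self._offsets_b[k + 1]] = np.bincount(
                codes, weights=v, minlength=self.q_per[k]
            )
        return out

    def _ztwz(self, w):
        H = np.zeros((self.q, self.q))
        for j, cj in enumerate(self.codes):
            oj = self._offsets_b[j]
            for k, ck in enumerate(self.codes):
                ok = self._offsets_b[k]
                np.add.at(H, (oj + cj, ok + ck), w)
        return H

    def _find_mode(self, beta, theta, sigmas, tol=1e-11, maxiter=100):
        """Newton ascent of the penalised joint log density over b."""
        d_inv = self._d_inv(sigmas)
        b = self._b_cache.copy()

        def joint(bv):
            eta = self._eta(beta, bv)
            return _nb2_loglike(self.y, eta, theta) - 0.5 * np.sum(d_inv * bv**2)

        g_old = joint(b)
        H = None
        for _ in range(maxiter):
            eta = self._eta(beta, b)
            u, w = _nb2_u_w(self.y, eta, theta)
            grad = self._zt(u) - d_inv * b
            H = self._ztwz(w)
            H[np.diag_indices_from(H)] += d_inv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                step = grad / np.diag(H)
            t = 1.0
            for _ in range(30):
                b_new = b + t * step
                g_new = joint(b_new)
                if g_new >= g_old - 1e-12:
                    break
                t *= 0.5
            if not np.isfinite(g_new):
                raise ConvergenceError("inner Newton diverged")
            delta = g_new - g_old
            b, g_old = b_new, g_new
            if abs(delta) < tol and np.max(np.abs(grad)) < 1e-6:
                break
        # recompute curvature at the mode
        eta = self._eta(beta, b)
        _, w = _nb2_u_w(self.y, eta, theta)
        H = self._ztwz(w)
        H[np.diag_indices_from(H)] += d_inv
        self._b_cache = b
        return b, g_old, H

    def loglike(self, beta, theta, sigmas):
        """Laplace-approximate marginal log likelihood."""
        if self.q == 0:
            return float(_nb2_loglike(self.y, self.X @ beta + self.offset, theta))
        b, g, H = self._find_mode(beta, theta, sigmas)
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:  # pragma: no cover - defensive
            raise ConvergenceError("indefinite curvature at the latent mode")
        logdet_d = 2.0 * np.sum(
            np.array(self.q_per) * np.log(np.asarray(sigmas, dtype=float))
        )
        return float(g - 0.5 * logdet_d - 0.5 * logdet_h)

    # -- outer optimisation ---------------------------------------------
    def _unpack(self, psi, fix_theta):
        p = self.X.shape[1]
        beta = psi[:p]
        if fix_theta is None:
            theta = np.exp(psi[p])
            sig = np.exp(psi[p + 1:])
        else:
            theta = fix_theta
            sig = np.exp(psi[p:])
        return beta, theta, sig

    def _start_beta(self):
        """Fixed-effect start values from a no-random-effect NB regression."""
        try:
            glm = sm.GLM(
                self.y, self.X, offset=self.offset,
                family=sm.families.NegativeBinomial(alpha=1.0),
            )
            return np.asarray(glm.fit(maxiter=200).params, dtype=float)
        except Exception:  # pragma: no cover - fallback for degenerate data
            try:
                glm = sm.GLM(self.y, self.X, offset=self.offset,
                             family=sm.families.Poisson())
                return np.asarray(glm.fit(maxiter=200).params, dtype=float)
            except Exception:
                return np.zeros(self.X.shape[1])

    def fit(self, start_params=None, fix_theta=None, tol=1e-8, maxiter=500) -> GLMMFit:
        p = self.X.shape[1]
        k = len(self.codes)
        if start_params is None:
            beta0 = self._start_beta()
            psi0 = list(beta0)
            if fix_theta is None:
                psi0.append(0.0)                      # theta = 1
            psi0.extend([np.log(0.1)] * k)            # sigma = 0.1
            psi0 = np.asarray(psi0)
        else:
            psi0 = np.asarray(start_params, dtype=float)
        bounds = [(None, None)] * p
        if fix_theta is None:
            bounds.append(self.THETA_LOG_BOUNDS)
        bounds.extend([self.SIGMA_LOG_BOUNDS] * k)

        trace = []

        def nll(psi):
            beta, theta, sig = self._unpack(psi, fix_theta)
            try:
                val = -self.loglike(beta, theta, sig)
            except (ConvergenceError, FloatingPointError, OverflowError):
                val = 1e12
            trace.append((psi.copy(), val))
            return val

        jac = None
        if self.q == 0:
            # pure NB regression: the score is available in closed form
            def jac(psi):
                beta, theta, _ = self._unpack(psi, fix_theta)
                eta = self.X @ beta + self.offset
                mu = np.exp(eta)
                u, _ = _nb2_u_w(self.y, eta, theta)
                g = [-self.X.T @ u]
                if fix_theta is None:
                    dtheta = np.sum(
                        digamma(self.y + theta) - digamma(theta)
                        + np.log(theta) + 1.0
                        - np.log(mu + theta) - (self.y + theta) / (mu + theta)
                    )
                    g.append(np.array([-theta * dtheta]))
                return np.concatenate(g)

        self._b_cache = np.zeros(self.q)
        res = scipy.optimize.minimize(
            nll, psi0, method="L-BFGS-B", bounds=bounds, jac=jac,
            options={"ftol": tol * 1e-5, "gtol": 1e-8, "maxiter": maxiter}
            if self.q == 0
            else {"ftol": tol * 1e-2, "gtol": 1e-7, "maxiter": maxiter,
                  "eps": 1e-5},
        )
        if not res.success:
            # a line-search failure at machine precision is fine if the
            # gradient is already flat; anything else is a real failure
            grad = np.atleast_1d(res.jac) if res.jac is not None else None
            flat = grad is not None and np.max(np.abs(grad)) < 1e-4 * (
                1.0 + abs(res.fun)
            )
            if not flat:
                raise ConvergenceError(
                    f"outer optimiser failed: {res.message}", trace=trace
                )
        psi_hat = res.x
        beta, theta, sig = self._unpack(psi_hat, fix_theta)

        # observed information of the full parameter vector, central differences
        cov, bse = self._observed_information(psi_hat, fix_theta)
        params = pd.Series(beta, index=self.exog_names)
        bse_s = pd.Series(bse[:p], index=self.exog_names)

        boundary = {}
        re_sd = {}
        ranef = {}
        for j, name in enumerate(self.group_names):
            re_sd[name] = float(sig[j])
            boundary[name] = bool(
                np.log(sig[j]) <= self.SIGMA_LOG_BOUNDS[0] + 1e-6
            )
        if self.q:
            b_hat, _, _ = self._find_mode(beta, theta, sig)
            for j, name in enumerate(self.group_names):
                seg = b_hat[self._offsets_b[j]:self._offsets_b[j + 1]]
                ranef[name] = pd.Series(seg, index=self.levels[j])
        llf = self.loglike(beta, theta, sig)
        return GLMMFit(
            params=params,
            bse=bse_s,
            theta=float(theta),
            re_sd=re_sd,
            llf=float(llf),
            n_obs=int(self.y.size),
            converged=bool(res.success),
            boundary=boundary,
            message=str(res.message),
            random_effects=ranef,
            optimizer_trace=res,
        )

    def _observed_information(self, psi, fix_theta):
        n = psi.size

        def f(v):
            beta, theta, sig = self._unpack(v, fix_theta)
            try:
                return -self.loglike(beta, theta, sig)
            except ConvergenceError:  # pragma: no cover
                return np.inf

        h = 1e-4 * np.maximum(1.0, np.abs(psi))
        H = np.zeros((n, n))
        f0 = f(psi)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                if i == j:
                    val = (f(psi + ei) - 2 * f0 + f(psi - ei)) / h[i] ** 2
                else:
                    val = (
                        f(psi + ei + ej) - f(psi + ei - ej)
                        - f(psi - ei + ej) + f(psi - ei - ej)
                    ) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov).copy()
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.linalg.pinv(H)
            diag = np.diag(cov).copy()
        bad = diag <= 0
        if np.any(bad):  # boundary parameters: SE undefined there
            diag[bad] = np.nan
        return cov, np.sqrt(diag)


# ---------------------------------------------------------------------------
# the two study models and the control contrasts


def _ensure_class(df, roster=None):
    out = df.copy()
    if "phenotype_class" not in out.columns:
        if "phenotype" in out.columns:
            out["phenotype_class"] = out["phenotype"].map(phenotype_class_of)
        elif roster is not None:
            ros = roster[["individual_id", "phenotype"]].copy()
            ros["phenotype_class"] = ros["phenotype"].map(phenotype_class_of)
            out = out.merge(ros[["individual_id", "phenotype_class"]],
                            on="individual_id", how="left")
        else:
            raise DataError("no phenotype information to derive phenotype_class")
    return out


def _design(df, predictor="phenotype_class"):
    if predictor == "phenotype_class":
        x = (df["phenotype_class"] == "trichromat").astype(float)
        name = "trichromat"
    elif predictor == "sex":
        x = (df["sex"].astype(str).str.lower().str[0] == "m").astype(float)
        name = "male"
    elif predictor == "allele_561":
        x = (df["phenotype"].astype(str) == "561").astype(float)
        name = "allele_561"
    else:
        raise DataError(f"unknown predictor {predictor!r}")
    X = pd.DataFrame({"intercept": np.ones(len(df)), name: x.to_numpy()})
    return X


def scan_model(
    scans: pd.DataFrame,
    re_structure: str = "crossed",
    min_cycles: int = 7,
    predictor: str = "phenotype_class",
    **fit_kwargs,
) -> GLMMFit:
    """Flower-foraging-scan frequency model.

    Response: flower scans per individual per cycle; offset: log total scans;
    fixed effect: the trichromat indicator; random intercepts for individual
    and cycle (crossed by default, ``re_structure="nested"`` nests cycle
    within individual).  Individuals with fewer than ``min_cycles`` cycles
    are excluded.
    """
    df = _ensure_class(scans)
    df = filter_eligible(df, min_cycles=min_cycles)
    if df.empty:
        raise DataError("no eligible individuals after the cycle filter")
    if (df["total_scans"] <= 0).any():
        n = int((df["total_scans"] <= 0).sum())
        log.info("scan_model: %d records with zero exposure excluded", n)
        df = df[df["total_scans"] > 0]
    if (df["flower_scans"] > df["total_scans"]).any():
        raise DataError("flower_scans exceeds total_scans")
    X = _design(df, predictor)
    if re_structure == "crossed":
        groups = {"individual": df["individual_id"], "cycle": df["cycle_id"]}
    elif re_structure == "nested":
        groups = {
            "individual": df["individual_id"],
            "individual:cycle": df["individual_id"].astype(str)
            + ":" + df["cycle_id"].astype(str),
        }
    elif re_structure == "individual":
        groups = {"individual": df["individual_id"]}
    else:
        raise DataError(f"unknown re_structure {re_structure!r}")
    model = NegativeBinomialGLMM(
        df["flower_scans"].to_numpy(),
        X,
        offset=np.log(df["total_scans"].to_numpy(float)),
        groups=groups,
    )
    return model.fit(**fit_kwargs)


def flpv_model(
    counts: pd.DataFrame,
    roster: pd.DataFrame,
    group_hours: pd.DataFrame,
    predictor: str = "phenotype_class",
    **fit_kwargs,
) -> GLMMFit:
    """Small-patch flower-patch-visit model.

    Response: total small-patch FLPVs per individual (from
    :func:`small_patch_filter`); offset: log of the observation hours of the
    individual's group; fixed effect: the trichromat indicator; random
    intercept for group.
    """
    ros = _ensure_class(roster)
    df = counts.merge(ros, on="individual_id", how="left")
    if df["phenotype_class"].isna().any():
        missing = df.loc[df["phenotype_class"].isna(), "individual_id"].tolist()
        raise DataError(f"individuals missing from roster: {missing[:5]}")
    df = df.merge(group_hours, on="group", how="left")
    if df["hours"].isna().any() or (df["hours"] <= 0).any():
        raise DataError("every group needs positive observation hours")
    X = _design(df, predictor)
    model = NegativeBinomialGLMM(
        df["n_flpv"].to_numpy(),
        X,
        offset=np.log(df["hours"].to_numpy(float)),
        groups={"group": df["group"]},
    )
    return model.fit(**fit_kwargs)


CONTRASTS = ("sex_within_561_dichromats", "females_only", "532_vs_561_males")


def control_contrasts(
    data: pd.DataFrame,
    contrast: str,
    kind: str = "scan",
    roster: pd.DataFrame | None = None,
    group_hours: pd.DataFrame | None = None,
    **fit_kwargs,
) -> GLMMFit:
    """Alternative-model contrasts controlling for sex and the 561 allele.

    ``sex_within_561_dichromats`` compares male vs female dichromats of the
    561 phenotype; ``females_only`` refits the phenotype-class contrast on
    females; ``532_vs_561_males`` compares dichromatic males of the 532 and
    561 phenotypes.  ``kind`` selects the scan-frequency or the FLPV model;
    the FLPV kind expects raw FLPV records plus ``roster`` and
    ``group_hours``.
    """
    if contrast not in CONTRASTS:
        raise DataError(f"unknown contrast {contrast!r}; choose from {CONTRASTS}")
    if kind == "flpv":
        if roster is None or group_hours is None:
            raise DataError("FLPV contrasts need roster and group_hours")
        ref = _ensure_class(roster)
    else:
        ref = _ensure_class(data)

    sex = ref.get("sex")
    if sex is None:
        raise DataError("contrast subsets need a sex column")
    sex = sex.astype(str).str.lower().str[0]
    pheno = ref["phenotype"].astype(str) if "phenotype" in ref.columns else None
    if pheno is None:
        raise DataError("contrast subsets need a phenotype column")

    if contrast == "sex_within_561_dichromats":
        mask = pheno == "561"
        predictor = "sex"
    elif contrast == "females_only":
        mask = sex == "f"
        predictor = "phenotype_class"
    else:  # 532_vs_561_males
        mask = (sex == "m") & pheno.isin(["532", "561"])
        predictor = "allele_561"
    if not mask.any():
        raise DataError(f"subset for contrast {contrast!r} is empty")

    if kind == "flpv":
        sub_roster = ref[mask]
        counts = small_patch_filter(data, roster=sub_roster)
        counts = counts[counts["individual_id"].isin(sub_roster["individual_id"])]
        return flpv_model(counts, sub_roster, group_hours,
                          predictor=predictor, **fit_kwargs)
    sub = ref[mask]
    if sub.empty:
        raise DataError(f"subset for contrast {contrast!r} is empty")
    return scan_model(sub, predictor=predictor, **fit_kwargs)
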