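"""Bayesian age-structured Cormack–Jolly–Seber (CJS) survival estimation.

Capture–resight histories (one 0/1 record per individual per annual
occasion, starting with a 1 at marking) are modelled with a state-space CJS
model: a latent alive indicator evolves by age- and year-specific apparent
survival Φ, and a marked, alive individual is resighted with year-specific
probability p shared by both age classes.  Individuals marked as chicks are
juvenile for their first two annual intervals after the 1-May hatch and
adult thereafter.

The sampler is a Gibbs sampler on the latent states: alive indicators after
an individual's last sighting are updated from their full conditionals, and
under Uniform(0,1) priors every Φ and p has a conjugate Beta full
conditional given the latent states.  Convergence is monitored with the
Gelman–Rubin potential scale reduction factor, accepting a fit only when
all R̂ of identifiable parameters are below 1.02.  The final-interval Φ and
final-occasion p are not separately identifiable in a CJS model and are
reported but flagged.

Histories are carried as a DataFrame with columns
``id, cohort, age_at_marking, h1..hK`` plus the ordered occasion years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .breeding import AveragedEstimates, all_subsets_average

JUV, AD = 0, 1


def history_matrix(histories: pd.DataFrame) -> np.ndarray:
    """0/1 encounter matrix (individuals × occasions) from the h1..hK columns."""
    hcols = sorted([c for c in histories.columns if c.startswith("h")],
                   key=lambda c: int(c[1:]))
    return histories[hcols].to_numpy(dtype=int)


def age_matrix(histories: pd.DataFrame, occasions) -> np.ndarray:
    """Age class (0 = juvenile, 1 = adult) per individual per annual interval.

    Interval ``t`` runs from occasion ``t`` to ``t+1`` (K-1 intervals for K
    occasions).  A bird marked as a juvenile in cohort year c (hatched
    1 May of c) is juvenile for the intervals starting in years c and c+1,
    and adult from the interval starting in c+2.  Birds marked as adults
    are adult throughout.
    """
    occasions = list(occasions)
    K = len(occasions)
    n = len(histories)
    ages = np.full((n, K - 1), AD, dtype=int)
    years = np.array(occasions[:-1])
    for i, (cohort, amark) in enumerate(
            zip(histories["cohort"], histories["age_at_marking"])):
        if cohort not in occasions:
            raise ValueError(f"cohort year {cohort} outside occasion range {occasions}")
        if str(amark) == "juvenile":
            ages[i, (years == cohort) | (years == cohort + 1)] = JUV
    return ages


def _first_occasions(histories: pd.DataFrame, occasions) -> np.ndarray:
    occasions = list(occasions)
    return np.array([occasions.index(c) for c in histories["cohort"]])


def cjs_loglik(h: np.ndarray, first: int, phi: np.ndarray, p: np.ndarray) -> float:
    """Marginal log-likelihood of one post-marking encounter history.

    ``phi[t]`` is the survival probability over interval t→t+1 resolved for
    this individual's age; ``p[t]`` the resighting probability at occasion
    t+1 (both length K-1).  Latent alive states are summed out: the history
    is certain-alive through its last 1, after which the χ recursion gives
    the probability of never being seen again.
    """
    h = np.asarray(h, dtype=int)
    K = len(h)
    if h[first] != 1:
        raise ValueError("history must start with 1 at the marking occasion")
    last = int(np.max(np.nonzero(h)[0]))
    ll = 0.0
    for t in range(first, last):
        ll += np.log(phi[t])
        ll += np.log(p[t]) if h[t + 1] == 1 else np.log1p(-p[t])
    # chi_t: P(never resighted after occasion t | alive at t)
    chi = 1.0
    for t in range(K - 2, last - 1, -1):
        chi = (1.0 - phi[t]) + phi[t] * (1.0 - p[t]) * chi
    return float(ll + np.log(chi))


def dataset_loglik(histories: pd.DataFrame, occasions, phi_juv, phi_ad, p) -> float:
    """Sum of per-individual CJS log-likelihoods for a history table."""
    H = history_matrix(histories)
    ages = age_matrix(histories, occasions)
    firsts = _first_occasions(histories, occasions)
    phi_juv = np.asarray(phi_juv, float)
    phi_ad = np.asarray(phi_ad, float)
    p = np.asarray(p, float)
    total = 0.0
    for i in range(len(H)):
        phi_i = np.where(ages[i] == JUV, phi_juv, phi_ad)
        total += cjs_loglik(H[i], int(firsts[i]), phi_i, p)
    return total


def gelman_rubin(chain_draws: np.ndarray) -> float:
    """Potential scale reduction factor R̂ for one parameter.

    ``chain_draws`` is (chains × draws).  R̂ = sqrt(((n-1)/n·W + B/n)/W)
    with W the mean within-chain variance and B = n·Var(chain means).
    Zero within-chain variance is undefined and returns NaN with a warning.
    """
    x = np.asarray(chain_draws, dtype=float)
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("gelman_rubin needs >=2 chains of >=2 draws")
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    if W == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined")
        return float("nan")
    B = n * float(np.var(np.mean(x, axis=1), ddof=1))
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class SurvivalPosterior:
    """Posterior draws and summaries of an age × year CJS fit.

    ``draws`` maps parameter name (phi_juv[year], phi_ad[year], p[year]) to
    a (chains × kept) array.  The summary has one row per parameter with the
    posterior median, central 95% credible interval, R̂ and an
    identifiability flag; ``converged`` is True when all identifiable R̂
    are below ``rhat_threshold``.
    """
    draws: dict
    summary: pd.DataFrame
    converged: bool
    rhat_threshold: float


def _gibbs_chain(H, firsts, lasts, ages, K, iters, burn, thin, rng):
    n = H.shape[0]
    nI = K - 1
    # initial values drawn from the prior
    phi = rng.uniform(size=(2, nI))  # rows: JUV, AD
    p = rng.uniform(size=nI)         # p[t] = resight prob at occasion t+1
    z = np.zeros((n, K), dtype=np.int8)
    for i in range(n):
        z[i, firsts[i]:lasts[i] + 1] = 1  # certain alive through last sighting

    kept = [i for i in range(iters) if i >= burn and (i - burn) % thin == 0]
    out_phi = np.empty((2, nI, len(kept)))
    out_p = np.empty((nI, len(kept)))
    ki = 0

    occ_after_first = firsts[:, None] < np.arange(K)[None, :]  # n×K: p applies
    for it in range(iters):
        # --- latent alive states after last sighting, single-site sweep ---
        for t in range(1, K):
            idx = np.nonzero(lasts < t)[0]
            if len(idx) == 0:
                continue
            prev = z[idx, t - 1].astype(float)
            phi_in = phi[ages[idx, t - 1], t - 1]
            a1 = prev * phi_in * (1.0 - p[t - 1])
            a0 = prev * (1.0 - phi_in) + (1.0 - prev)
            if t <= K - 2:
                nxt = z[idx, t + 1].astype(float)
                phi_out = phi[ages[idx, t], t]
                a1 *= nxt * phi_out + (1.0 - nxt) * (1.0 - phi_out)
                a0 *= (1.0 - nxt)  # dead birds stay dead
            pr = np.where(a1 + a0 > 0, a1 / np.maximum(a1 + a0, 1e-300), 0.0)
            z[idx, t] = rng.random(len(idx)) < pr

        # --- conjugate Beta updates under Uniform(0,1) priors ---
        for t in range(nI):
            at_risk = (z[:, t] == 1) & (firsts <= t)
            surv = z[:, t + 1] == 1
            for a in (JUV, AD):
                sel = at_risk & (ages[:, t] == a)
                n_risk = int(sel.sum())
                n_surv = int((sel & surv).sum())
                phi[a, t] = rng.beta(1 + n_surv, 1 + n_risk - n_surv)
            obs = (z[:, t + 1] == 1) & occ_after_first[:, t + 1]
            n_obs = int(obs.sum())
            n_det = int(H[obs, t + 1].sum())
            p[t] = rng.beta(1 + n_det, 1 + n_obs - n_det)

        if it >= burn and (it - burn) % thin == 0:
            out_phi[:, :, ki] = phi
            out_p[:, ki] = p
            ki += 1
    return out_phi, out_p


class BayesianCJS(BaseEstimator):
    """Gibbs-sampled Bayesian CJS model with a fixed age effect in survival.

    Parameters
    ----------
    chains : int, default 3
    iters : int, default 10000
        Iterations per chain; the first ``burn`` are discarded and the rest
        thinned by ``thin`` (defaults keep 834 draws per chain).
    burn : int, default 5000
    thin : int, default 6
    rhat_threshold : float, default 1.02
        A fit is accepted when every identifiable parameter's R̂ is below
        this value.
    age_model : {"interaction"}, default "interaction"
        Separate juvenile and adult survival series per year (age × year).
    random_state : int or None
        Seed; the same seed yields bit-identical draws.

    Attributes (after ``fit``)
    --------------------------
    posterior_ : :class:`SurvivalPosterior`
    summary_ : DataFrame (parameter, median, lower95, upper95, rhat, identifiable)
    converged_ : bool
    annual_survival_ : DataFrame of posterior-median Φ per age class and year.
    """

    def __init__(self, chains: int = 3, iters: int = 10000, burn: int = 5000,
                 thin: int = 6, rhat_threshold: float = 1.02,
                 age_model: str = "interaction", random_state=None):
        self.chains = chains
        self.iters = iters
        self.burn = burn
        self.thin = thin
        self.rhat_threshold = rhat_threshold
        self.age_model = age_model
        self.random_state = random_state

    def fit(self, histories: pd.DataFrame, occasions):
        occasions = list(occasions)
        K = len(occasions)
        if K < 2 or len(histories) == 0:
            raise ValueError("need at least one history over at least two occasions")
        if self.age_model != "interaction":
            raise ValueError("only the age x year ('interaction') model is implemented")
        H = history_matrix(histories)
        if H.shape[1] != K:
            raise ValueError("history length does not match number of occasions")
        ages = age_matrix(histories, occasions)
        firsts = _first_occasions(histories, occasions)
        if np.any(H[np.arange(len(H)), firsts] != 1):
            raise ValueError("every history must have a 1 at its marking occasion")
        lasts = np.array([int(np.max(np.nonzero(r)[0])) for r in H])
        nI = K - 1

        ss = np.random.SeedSequence(self.random_state)
        chain_phi, chain_p = [], []
        for child in ss.spawn(self.chains):
            rng = np.random.default_rng(child)
            out_phi, out_p = _gibbs_chain(H, firsts, lasts, ages, K,
                                          self.iters, self.burn, self.thin, rng)
            chain_phi.append(out_phi)
            chain_p.append(out_p)
        phi_draws = np.stack(chain_phi)  # chains × 2 × nI × kept
        p_draws = np.stack(chain_p)      # chains × nI × kept

        juv_possible = np.array([(ages[:, t] == JUV).any() for t in range(nI)])
        draws, rows = {}, []

        def add(name, mat, identifiable):
            draws[name] = mat
            flat = mat.ravel()
            lo, med, hi = np.percentile(flat, [2.5, 50, 97.5])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = gelman_rubin(mat)
            rows.append({"parameter": name, "median": med, "lower95": lo,
                         "upper95": hi, "rhat": rhat, "identifiable": identifiable})

        for t in range(nI):
            yr = occasions[t]
            ident = t < nI - 1  # final interval confounded with final p
            if juv_possible[t]:
                add(f"phi_juv[{yr}]", phi_draws[:, JUV, t, :], ident)
            add(f"phi_ad[{yr}]", phi_draws[:, AD, t, :], ident)
            add(f"p[{occasions[t + 1]}]", p_draws[:, t, :], t < nI - 1)

        summary = pd.DataFrame(rows)
        ident_rhats = summary.loc[summary["identifiable"], "rhat"]
        converged = bool(np.all(ident_rhats < self.rhat_threshold))
        self.posterior_ = SurvivalPosterior(draws=draws, summary=summary,
                                            converged=converged,
                                            rhat_threshold=self.rhat_threshold)
        self.summary_ = summary
        self.converged_ = converged
        ann = summary[summary["parameter"].str.startswith("phi")].copy()
        ann["age"] = np.where(ann["parameter"].str.startswith("phi_juv"),
                              "juvenile", "adult")
        ann["year"] = ann["parameter"].str.extract(r"\[(\d+)\]").astype(int)
        self.annual_survival_ = ann[["age", "year", "median", "lower95",
                                     "upper95", "identifiable"]].reset_index(drop=True)
        self.occasions_ = occasions
        return self


def fit_cjs(histories: pd.DataFrame, occasions, chains: int = 3,
            iters: int = 10000, burn: int = 5000, thin: int = 6,
            seed=None) -> SurvivalPosterior:
    """Functional wrapper over :class:`BayesianCJS`."""
    model = BayesianCJS(chains=chains, iters=iters, burn=burn, thin=thin,
                        random_state=seed).fit(histories, occasions)
    return model.posterior_


def survival_vs_pcs(annual_estimates: pd.DataFrame, pc_scores: pd.DataFrame,
                    n_pcs: int = 5) -> dict:
    """All-subsets Gaussian model averaging of annual survival on PC scores.

    ``annual_estimates`` needs columns ``age, year, median``; ``pc_scores``
    is indexed by year with PC columns.  One averaging run per age class;
    returns a dict age → :class:`AveragedEstimates`.  Warns when the subset
    dimension approaches the number of years.
    """
    pcs = pc_scores.iloc[:, :n_pcs]
    out = {}
    for age, g in annual_estimates.groupby("age"):
        g = g.set_index("year").join(pcs, how="inner")
        if n_pcs > len(g) - 1:
            warnings.warn(f"{age}: {n_pcs} predictors for {len(g)} years; "
                          "full model is rank deficient")
        out[age] = all_subsets_average(g["median"].to_numpy(),
                                       g[pcs.columns], family="gaussian")
    return out
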