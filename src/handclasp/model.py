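"""The generative probability model for dyadic handclasp style choice.

Each individual *i* in group *j* carries a preference vector W_ij over the
five style variants, expressed relative to the wrist reference category
(W_ij1 = 0).  Conditional on being the one who chooses, the probability of
performing variant k is the softmax

    p_ijk = exp(W_ijk) / sum_l exp(W_ijl).

Preferences are hierarchically pooled: W_ijk ~ Normal(mu_jk, sigma_W) for
k = 2..5, where mu_jk is the group mean preference.  Because a handclasp is
dyadic, the observed pair of variants for event e arises from one of three
latent situations: (a) both performers choose independently, (b) performer 1
chooses and the partner matches, (c) performer 2 chooses.  The situation
probabilities are driven by each performer's positive influence score

    I_ij = exp(I_RE,ij + beta_age * age_ij + beta_sex * sex_ij + beta_rank * rank_ij)

via (pi_a, pi_b, pi_c) = (exp(beta_a), I_1, I_2) / (exp(beta_a) + I_1 + I_2).
The latent situation indicators are marginalized analytically:

    P(y1, y2) = pi_a p1(y1) p2(y2) + 1{y1 = y2} [pi_b p1(y1) + pi_c p2(y2)].

Model variants:

* ``baseline``  — one preference vector per individual, single sigma_W.
* ``maternal``  — preference prior mean interpolates toward the mother's
  vector, W_ijk ~ Normal((1 - m) mu_jk + m W_M(ij)k, sigma_W), with separate
  maternal weights m for the young (<= threshold) and old age categories;
  unknown mothers receive an imputed latent vector ~ Normal(mu_jk, sigma_W).
* ``agesplit``  — individuals carry separate preference vectors per age
  category, with category-specific sigma_W (young vs old), so that
  convergence toward the group style with age appears as sigma_young >
  sigma_old.
* ``combined``  — maternal and age-split extensions together.

Hyperpriors: mu_jk and every beta ~ Normal(0, variance 1000); sigma_W and
sigma_I ~ Uniform(0, 10); maternal weights ~ Uniform(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import Dataset, N_VARIANTS

VARIANTS = ("baseline", "maternal", "agesplit", "combined")
#: age-category indices used throughout (slot tables, sigma_W pairs, m pairs)
YOUNG, OLD = 0, 1


@dataclass
class ModelSpec:
    """Which model variant is fitted, plus priors and covariate coding.

    Parameters
    ----------
    variant : one of ``baseline``, ``maternal``, ``agesplit``, ``combined``.
    age_threshold : years; ages <= threshold count as the young category.
    mu_prior_sd : prior SD of group means and influence coefficients.  The
        source convention "N(0,1000)" is read as variance 1000 (SD ~ 31.6);
        a precision-1000 reading would be a near point mass, contradicting
        the stated vagueness.
    sigma_upper : upper bound of the Uniform(0, upper) priors on sigma_W and
        sigma_I.
    """

    variant: Literal["baseline", "maternal", "agesplit", "combined"] = "baseline"
    age_threshold: float = 8.0
    mu_prior_sd: float = float(np.sqrt(1000.0))
    sigma_upper: float = 10.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")

    @property
    def split_sigma(self) -> bool:
        return self.variant in ("agesplit", "combined")

    @property
    def maternal(self) -> bool:
        return self.variant in ("maternal", "combined")

    @property
    def split_preferences(self) -> bool:
        """Whether individuals carry one preference vector per age category."""
        return self.variant != "baseline"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# Core probability operations
# ---------------------------------------------------------------------------

def preference_probs(W: np.ndarray) -> np.ndarray:
    """Softmax of a preference vector (first entry 0 by convention).

    Works on the last axis; stable under adding a constant to all entries
    (max-subtraction).
    """
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("preference vector contains non-finite entries")
    z = W - W.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def influence(age_std: float, sex: int, rank_norm: float,
              beta_age: float, beta_sex: float, beta_rank: float,
              individual_re: float = 0.0) -> float:
    """Positive influence score I = exp(RE + b_age*age + b_sex*sex + b_rank*rank)."""
    lin = individual_re + beta_age * age_std + beta_sex * sex + beta_rank * rank_norm
    if not np.all(np.isfinite(lin)):
        raise ValueError("non-finite influence linear predictor")
    return np.exp(lin)


def chooser_probs(I1: float, I2: float, beta_a: float) -> np.ndarray:
    """Probabilities of the three latent chooser situations (a, b, c).

    (pi_a, pi_b, pi_c) = (exp(beta_a), I1, I2) / (exp(beta_a) + I1 + I2).
    """
    I1, I2 = float(I1), float(I2)
    if I1 < 0 or I2 < 0:
        raise ValueError("influence scores must be non-negative")
    ea = np.exp(float(beta_a))
    D = ea + I1 + I2
    return np.array([ea / D, I1 / D, I2 / D])


def event_pair_loglik(y1: int, y2: int, p1: Sequence[float], p2: Sequence[float],
                      pi: Sequence[float]) -> float:
    """Log probability of the observed variant pair, latent chooser marginalized.

    ``y1``/``y2`` are variant codes in 1..5.  Situations b and c can only
    produce matching variants, so for a discordant pair only the independent
    term survives.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pi = np.asarray(pi, dtype=float)
    k1, k2 = int(y1) - 1, int(y2) - 1
    prob = pi[0] * p1[k1] * p2[k2]
    if k1 == k2:
        prob += pi[1] * p1[k1] + pi[2] * p2[k2]
    if prob <= 0.0:
        return -np.inf
    return float(np.log(prob))


def preference_prior_logdensity(W_i: Sequence[float], mu_j: Sequence[float],
                                sigma_W: float, variant: str = "baseline",
                                W_mother: Sequence[float] | None = None,
                                m: float = 0.0) -> float:
    """Log density of one preference vector under its hierarchical prior.

    Baseline: sum over k = 2..5 of Normal(W_ik | mu_jk, sigma_W).  Maternal:
    the mean is (1 - m) mu_jk + m W_M(ij)k.  Only the non-reference entries
    carry density; the first entry of every vector must be 0.
    """
    if sigma_W <= 0:
        raise ValueError("sigma_W must be positive")
    W_i = np.asarray(W_i, dtype=float)
    mu_j = np.asarray(mu_j, dtype=float)
    if W_i[0] != 0.0 or mu_j[0] != 0.0:
        raise ValueError("reference-category entries must be 0")
    if variant == "maternal":
        if W_mother is None:
            raise ValueError("maternal variant requires the mother's preference vector")
        if not 0.0 <= m <= 1.0:
            raise ValueError("maternal weight m must lie in [0, 1]")
        mean = (1.0 - m) * mu_j[1:] + m * np.asarray(W_mother, dtype=float)[1:]
    else:
        mean = mu_j[1:]
    resid = W_i[1:] - mean
    return float(-0.5 * np.sum(resid ** 2) / sigma_W ** 2
                 - 4 * np.log(sigma_W) - 2.0 * np.log(2.0 * np.pi))


def group_mean_transform(mu_j: np.ndarray) -> np.ndarray:
    """Expected variant proportions for an average group member: softmax(mu_j).

    Applied per MCMC iteration, this turns the reference-coded group means
    into directly comparable probability simplices.
    """
    return preference_probs(mu_j)


# ---------------------------------------------------------------------------
# Model arrays: index structures shared by the sampler and log_posterior
# ---------------------------------------------------------------------------

@dataclass
class ModelArrays:
    """Flattened index arrays for one (dataset, spec) pair.

    A *slot* is one preference vector: per individual in the baseline
    variant, per (individual, age category) otherwise, plus latent vectors
    for unknown mothers in the maternal variants.
    """

    spec: ModelSpec
    n_groups: int
    n_individuals: int
    individual_ids: list
    # slots
    slots: pd.DataFrame            # columns: individual_id, group, age_cat, sigma_idx, mother_slot, m_cat, imputed
    slot_group: np.ndarray
    slot_sigma_idx: np.ndarray
    slot_mother: np.ndarray        # -1 when the prior has no maternal term
    slot_mcat: np.ndarray          # which maternal weight applies (YOUNG/OLD); -1 without mother
    # events
    y1: np.ndarray                 # 0-based variant index
    y2: np.ndarray
    s1: np.ndarray                 # slot of performer 1
    s2: np.ndarray
    i1: np.ndarray                 # individual index of performer 1
    i2: np.ndarray
    X1: np.ndarray                 # (E, 3): age_std, sex, rank_norm
    X2: np.ndarray
    concordant: np.ndarray
    # adjacency
    slot_events: list = field(default_factory=list)   # per slot: (events as performer1, as performer2)
    indiv_events: list = field(default_factory=list)  # per individual: same split
    children: list = field(default_factory=list)      # per slot: child slots referencing it as mother

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def n_events(self) -> int:
        return len(self.y1)

    @property
    def n_sigma(self) -> int:
        return 2 if self.spec.split_sigma else 1


def build_model_arrays(dataset: Dataset, spec: ModelSpec) -> ModelArrays:
    """Compile a dataset into the flat index arrays the likelihood uses."""
    cov = dataset.covariates(age_threshold=spec.age_threshold)
    ind = dataset.individuals
    groups = sorted(ind["group"].unique()) if len(ind) else list(range(1, dataset.n_groups + 1))
    group_idx = {g: i for i, g in enumerate(groups)}
    n_groups = max(len(groups), dataset.n_groups)
    individual_ids = list(ind["id"])
    indiv_idx = {iid: i for i, iid in enumerate(individual_ids)}
    info = ind.set_index("id") if len(ind) else None

    cat_code = {"young": YOUNG, "old": OLD}
    # observed age categories per individual
    cats_of: dict[str, set] = {iid: set() for iid in individual_ids}
    for iid, cat in zip(cov["individual_id"], cov["age_cat"]):
        cats_of[iid].add(cat_code[cat])

    # --- slot table ---------------------------------------------------------
    rows = []
    slot_of: dict[tuple, int] = {}

    def add_slot(iid, group, cat, imputed=False):
        key = (iid, cat)
        if key in slot_of:
            return slot_of[key]
        slot_of[key] = len(rows)
        rows.append({"individual_id": iid, "group": group, "age_cat": cat,
                     "sigma_idx": (cat if spec.split_sigma else 0),
                     "mother_slot": -1, "m_cat": -1, "imputed": imputed})
        return slot_of[key]

    for iid in individual_ids:
        g = group_idx[info.loc[iid, "group"]]
        if spec.split_preferences:
            for cat in sorted(cats_of[iid]) or [OLD]:
                add_slot(iid, g, cat)
            if not cats_of[iid]:
                add_slot(iid, g, OLD)
        else:
            add_slot(iid, g, -1)

    if spec.maternal:
        # resolve mother links; unknown mothers get an imputed latent slot
        for iid in individual_ids:
            mid = info.loc[iid, "mother_id"]
            g = group_idx[info.loc[iid, "group"]]
            if mid is not None and not (isinstance(mid, float) and np.isnan(mid)) and mid in indiv_idx:
                mkey = (mid, OLD) if (mid, OLD) in slot_of else (mid, min(cats_of[mid] or {OLD}))
                mslot = slot_of[mkey]
            elif mid is not None and not (isinstance(mid, float) and np.isnan(mid)):
                mslot = add_slot(f"{mid}", g, OLD, imputed=True)
            else:
                mslot = -1
            if mslot >= 0:
                for cat in (cats_of[iid] or {OLD}):
                    s = slot_of[(iid, cat)]
                    rows[s]["mother_slot"] = mslot
                    rows[s]["m_cat"] = cat

    slots = pd.DataFrame(rows, columns=["individual_id", "group", "age_cat",
                                        "sigma_idx", "mother_slot", "m_cat", "imputed"])
    S = len(slots)

    # --- events -------------------------------------------------------------
    ev = dataset.events
    E = len(ev)
    y1 = ev["y_g1"].to_numpy(dtype=np.int64) - 1 if E else np.empty(0, dtype=np.int64)
    y2 = ev["y_g2"].to_numpy(dtype=np.int64) - 1 if E else np.empty(0, dtype=np.int64)
    s_1 = np.empty(E, dtype=np.int64)
    s_2 = np.empty(E, dtype=np.int64)
    i_1 = np.empty(E, dtype=np.int64)
    i_2 = np.empty(E, dtype=np.int64)
    X1 = np.empty((E, 3))
    X2 = np.empty((E, 3))
    if E:
        cov_key = cov.set_index(["individual_id", "window_id"])
        for n, (w, a, b) in enumerate(zip(ev["window_id"], ev["g1_id"], ev["g2_id"])):
            for side, iid, s_arr, i_arr, X in ((0, a, s_1, i_1, X1), (1, b, s_2, i_2, X2)):
                try:
                    row = cov_key.loc[(iid, w)]
                except KeyError:
                    raise ValueError(f"no covariates for individual {iid!r} in window {w!r}") from None
                cat = cat_code[row["age_cat"]] if spec.split_preferences else -1
                s_arr[n] = slot_of[(iid, cat)]
                i_arr[n] = indiv_idx[iid]
                X[n, 0] = row["age_std"]
                X[n, 1] = row["sex"]
                X[n, 2] = row["rank_norm"]

    arrays = ModelArrays(
        spec=spec, n_groups=n_groups, n_individuals=len(individual_ids),
        individual_ids=individual_ids, slots=slots,
        slot_group=slots["group"].to_numpy(dtype=np.int64),
        slot_sigma_idx=slots["sigma_idx"].to_numpy(dtype=np.int64),
        slot_mother=slots["mother_slot"].to_numpy(dtype=np.int64),
        slot_mcat=slots["m_cat"].to_numpy(dtype=np.int64),
        y1=y1, y2=y2, s1=s_1, s2=s_2, i1=i_1, i2=i_2, X1=X1, X2=X2,
        concordant=(y1 == y2),
    )
    arrays.slot_events = [
        (np.flatnonzero(s_1 == s), np.flatnonzero(s_2 == s)) for s in range(S)
    ]
    arrays.indiv_events = [
        (np.flatnonzero(i_1 == i), np.flatnonzero(i_2 == i))
        for i in range(len(individual_ids))
    ]
    arrays.children = [np.flatnonzero(arrays.slot_mother == s) for s in range(S)]
    return arrays


# ---------------------------------------------------------------------------
# Reference log posterior (direct, uncached)
# ---------------------------------------------------------------------------

def _norm_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def slot_prior_means(arrays: ModelArrays, W: np.ndarray, mu: np.ndarray,
                     m: np.ndarray) -> np.ndarray:
    """Prior mean of every slot's non-reference entries, shape (S, 4)."""
    mean = mu[arrays.slot_group, 1:].copy()
    has = arrays.slot_mother >= 0
    if has.any():
        mm = m[arrays.slot_mcat[has]][:, None]
        mean[has] = (1 - mm) * mean[has] + mm * W[arrays.slot_mother[has], 1:]
    return mean


def log_posterior(params: dict, dataset: Dataset, spec: ModelSpec,
                  arrays: ModelArrays | None = None) -> float:
    """Log posterior density (up to the constant normalizer) at one point.

    ``params`` holds: ``mu`` (J, 5) with column 0 zero, ``W`` (S, 5),
    ``beta`` (4,) ordered (beta_a, beta_age, beta_sex, beta_rank), ``I_RE``
    (N,), ``sigma_W`` (1 or 2,), ``sigma_I`` scalar, and for maternal
    variants ``m`` (2,) ordered (young, old).  Returns -inf outside the
    prior support.  This direct implementation is the reference the
    incremental sampler is tested against.
    """
    if arrays is None:
        arrays = build_model_arrays(dataset, spec)
    mu = np.asarray(params["mu"], dtype=float)
    W = np.asarray(params["W"], dtype=float)
    beta = np.asarray(params["beta"], dtype=float)
    I_RE = np.asarray(params.get("I_RE", np.zeros(arrays.n_individuals)), dtype=float)
    sigma_W = np.atleast_1d(np.asarray(params["sigma_W"], dtype=float))
    sigma_I = float(params.get("sigma_I", 1.0))
    m = np.asarray(params.get("m", np.zeros(2)), dtype=float)

    if np.any(sigma_W <= 0) or np.any(sigma_W >= spec.sigma_upper):
        return -np.inf
    if sigma_I <= 0 or sigma_I >= spec.sigma_upper:
        return -np.inf
    if spec.maternal and (np.any(m < 0) or np.any(m > 1)):
        return -np.inf

    lp = 0.0
    # hyperpriors
    lp += _norm_logpdf(mu[:, 1:], 0.0, spec.mu_prior_sd).sum()
    lp += _norm_logpdf(beta, 0.0, spec.mu_prior_sd).sum()
    lp -= np.log(spec.sigma_upper) * (len(sigma_W) + 1)   # uniform sigmas
    # preference prior
    if arrays.n_slots:
        means = slot_prior_means(arrays, W, mu, m)
        sds = sigma_W[arrays.slot_sigma_idx][:, None]
        lp += _norm_logpdf(W[:, 1:], means, sds).sum()
    # influence random effects
    if arrays.n_individuals:
        lp += _norm_logpdf(I_RE, 0.0, sigma_I).sum()
    # events
    if arrays.n_events:
        logP = W - logsumexp(W, axis=1, keepdims=True)
        lp1 = logP[arrays.s1, arrays.y1]
        lp2 = logP[arrays.s2, arrays.y2]
        li1 = I_RE[arrays.i1] + arrays.X1 @ beta[1:]
        li2 = I_RE[arrays.i2] + arrays.X2 @ beta[1:]
        lD = np.logaddexp(beta[0], np.logaddexp(li1, li2))
        la, lb, lc = beta[0] - lD, li1 - lD, li2 - lD
        both = la + lp1 + lp2
        ell = both.copy()
        conc = arrays.concordant
        if conc.any():
            stack = np.stack([both[conc], lb[conc] + lp1[conc], lc[conc] + lp2[conc]])
            ell[conc] = logsumexp(stack, axis=0)
        lp += ell.sum()
    return float(lp)
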