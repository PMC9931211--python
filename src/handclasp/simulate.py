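"""Forward simulator of chimpanzee populations and handclasp events.

The generator draws populations and dyadic events under exactly the
generative model the inference machinery fits — hierarchical preference
vectors, influence-driven latent chooser situations, maternal interpolation
and age-split dispersion when requested — and keeps a ground-truth ledger
(generating parameters, per-slot preference vectors, per-event latent
situation and chooser identity) that the fitting pipeline never reads.  It
stands in for the study's observational data, which were not deposited, and
its defaults emulate the published study conditions: two groups totalling 71
individuals, five observation windows spanning 2007-2019, 2049 events (4098
style productions), ages 5-33 years over the study, group style preferences
matching the published between-group contrast, and transmission-bias
parameters set to the published posterior means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset
from .model import ModelSpec, preference_probs, chooser_probs, YOUNG, OLD

#: Expected variant proportions per group used to derive the default true
#: group mean preferences (log-ratio to the wrist reference category).  They
#: reproduce the published between-group contrast: palm most popular in both
#: groups but far more dominant in group 2, wrist and elbow favored in group 1.
DEFAULT_GROUP_PREFS = (
    (0.341, 0.013, 0.024, 0.008, 0.615),
    (0.128, 0.001, 0.009, 0.003, 0.859),
)

SITUATIONS = ("a", "b", "c")


def prefs_to_mu(prefs) -> np.ndarray:
    """Convert variant proportion vectors to reference-coded group means."""
    p = np.asarray(prefs, dtype=float)
    mu = np.log(p / p[:, :1])
    mu[:, 0] = 0.0
    return mu


@dataclass
class SimulationConfig:
    """True parameters and design of one synthetic study.

    Defaults are the study conditions the model family was published under;
    the transmission-bias truths (beta_rank = 2.78, beta_age = 0.440,
    beta_sex = 0.460, sigma_I = 0.5, m = (0.259, 0.425), age-split sigmas
    (2.37, 1.02)) are the published posterior means, and the default group
    preference contrast matches the published group preference table.
    """

    variant: str = "baseline"
    age_threshold: float = 8.0
    group_sizes: tuple = (36, 35)
    window_years: tuple = (2007, 2010, 2011, 2017, 2019)
    n_events: int = 2049
    # demography
    age_min: float = 5.0            # age at the first window
    age_max: float = 21.0           # so ages span 5-33 over the study
    p_male: float = 26 / 71
    p_mother_known: float = 0.4
    mother_age_gap: float = 10.0
    # preference truths
    group_prefs: tuple = DEFAULT_GROUP_PREFS
    sigma_W: float = 1.0
    sigma_W_young: float = 2.37
    sigma_W_old: float = 1.02
    m_young: float = 0.259
    m_old: float = 0.425
    # influence truths
    beta_a: float = 1.0
    beta_age: float = 0.440
    beta_sex: float = 0.460
    beta_rank: float = 2.78
    sigma_I: float = 0.5
    # rank process
    rank_age_weight: float = 0.3
    rank_noise_sd: float = 3.0
    # dyad sampling: None = uniform within group, else Dirichlet concentration
    # for random persistent partner-affinity weights
    partner_affinity: float | None = None

    def __post_init__(self) -> None:
        if self.n_events < 0 or any(n <= 1 for n in self.group_sizes):
            raise ValueError("need at least 2 individuals per group and n_events >= 0")
        if not (0 <= self.m_young <= 1 and 0 <= self.m_old <= 1):
            raise ValueError("maternal weights must lie in [0, 1]")
        for s in (self.sigma_W, self.sigma_W_young, self.sigma_W_old, self.sigma_I):
            if not 0 <= s < 10:
                raise ValueError("sigma truths must lie inside the prior support [0, 10)")

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(variant=self.variant, age_threshold=self.age_threshold)

    @property
    def mu_true(self) -> np.ndarray:
        return prefs_to_mu(self.group_prefs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("group_sizes", "window_years"):
            if key in d:
                d[key] = tuple(d[key])
        if "group_prefs" in d:
            d["group_prefs"] = tuple(tuple(row) for row in d["group_prefs"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generating parameters and latent states of one synthetic dataset."""

    config: dict
    mu: list
    W: pd.DataFrame                  # individual_id, age_cat, W1..W5
    I_RE: dict
    situations: pd.DataFrame         # event_id, situation, chooser_id

    def params(self) -> dict:
        c = self.config
        return {"mu": np.asarray(self.mu), "beta_a": c["beta_a"],
                "beta_age": c["beta_age"], "beta_sex": c["beta_sex"],
                "beta_rank": c["beta_rank"], "sigma_I": c["sigma_I"],
                "sigma_W": c["sigma_W"], "sigma_W_young": c["sigma_W_young"],
                "sigma_W_old": c["sigma_W_old"], "m_young": c["m_young"],
                "m_old": c["m_old"]}

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "mu": self.mu,
            "W": self.W.to_dict(orient="list"),
            "I_RE": self.I_RE,
            "situations": self.situations.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(config=payload["config"], mu=payload["mu"],
                   W=pd.DataFrame(payload["W"]), I_RE=payload["I_RE"],
                   situations=pd.DataFrame(payload["situations"]))


@dataclass
class Population:
    individuals: pd.DataFrame
    windows: pd.DataFrame
    ranks: pd.DataFrame
    covariates: pd.DataFrame
    W: pd.DataFrame                  # truth, one row per preference slot
    I_RE: dict
    config: SimulationConfig

    def slot_W(self, individual_id: str, age_cat: int) -> np.ndarray:
        sel = self.W[(self.W["individual_id"] == individual_id)
                     & (self.W["age_cat"] == age_cat)]
        if not len(sel):
            raise KeyError((individual_id, age_cat))
        return sel[[f"W{k}" for k in range(1, 6)]].to_numpy(dtype=float)[0]


# ---------------------------------------------------------------------------

def _rater_assessments(true_order: np.ndarray, n_raters: int, rng) -> np.ndarray:
    """Noisy ordinal ranks: independent +/-1 jitter per rater, then re-ranked."""
    n = len(true_order)
    out = np.empty((n_raters, n), dtype=np.int64)
    for r in range(n_raters):
        scores = true_order + rng.integers(-1, 2, size=n)
        order = np.lexsort((rng.random(n), scores))
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(1, n + 1)
        out[r] = ranks
    return out


def simulate_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Draw individuals, windows, rank assessments, covariates, and true preferences."""
    J = len(config.group_sizes)
    mu = config.mu_true
    if mu.shape != (J, 5):
        raise ValueError("group_prefs shape does not match the number of groups")
    spec = config.spec
    y0 = config.window_years[0]

    rows = []
    for j, n in enumerate(config.group_sizes):
        for i in range(n):
            iid = f"g{j + 1}i{i + 1:02d}"
            rows.append({"id": iid, "group": j + 1,
                         "sex": int(rng.random() < config.p_male),
                         "mother_id": None,
                         "birth_year": float(y0 - np.round(
                             rng.uniform(config.age_min, config.age_max), 1))})
    individuals = pd.DataFrame(rows, columns=["id", "group", "sex", "mother_id", "birth_year"])

    # matrilines: a known mother is a female of the same group at least
    # `mother_age_gap` years older
    for j in range(J):
        sub = individuals[individuals["group"] == j + 1]
        for idx in sub.index:
            if rng.random() >= config.p_mother_known:
                continue
            byear = individuals.at[idx, "birth_year"]
            eligible = sub[(sub["sex"] == 0)
                           & (sub["birth_year"] <= byear - config.mother_age_gap)
                           & (sub.index != idx)]
            if len(eligible):
                individuals.at[idx, "mother_id"] = eligible["id"].iloc[
                    rng.integers(len(eligible))]

    windows = pd.DataFrame({
        "window_id": [f"w{t + 1}" for t in range(len(config.window_years))],
        "year": [float(y) for y in config.window_years]})

    # dominance: latent score increases with age plus individual noise; three
    # caretakers provide jittered ordinal assessments per window
    rank_rows = []
    base_noise = {iid: rng.normal(0.0, config.rank_noise_sd)
                  for iid in individuals["id"]}
    for _, w in windows.iterrows():
        for j in range(J):
            sub = individuals[individuals["group"] == j + 1]
            ages = w["year"] - sub["birth_year"].to_numpy()
            score = config.rank_age_weight * ages + np.array(
                [base_noise[i] for i in sub["id"]])
            order = np.empty(len(sub), dtype=np.int64)   # 1 = highest score
            srt = np.argsort(-score, kind="stable")
            order[srt] = np.arange(1, len(sub) + 1)
            for attempt in range(100):
                assess = _rater_assessments(order, 3, rng)
                if len(np.unique(assess.mean(axis=0))) > 1:
                    break
            for r in range(3):
                for iid, rk in zip(sub["id"], assess[r]):
                    rank_rows.append({"window_id": w["window_id"],
                                      "individual_id": iid,
                                      "rater_id": f"r{r + 1}",
                                      "ordinal_rank": int(rk)})
    ranks = pd.DataFrame(rank_rows, columns=["window_id", "individual_id",
                                             "rater_id", "ordinal_rank"])

    dataset = Dataset(individuals=individuals, windows=windows, ranks=ranks,
                      events=pd.DataFrame(columns=["event_id", "window_id", "g1_id",
                                                   "g2_id", "y_g1", "y_g2"]))
    cov = dataset.covariates(age_threshold=config.age_threshold)

    # true preference vectors, mothers drawn before offspring (age order)
    cats_of = {iid: set() for iid in individuals["id"]}
    for iid, cat in zip(cov["individual_id"], cov["age_cat"]):
        cats_of[iid].add(YOUNG if cat == "young" else OLD)
    sig_of = {YOUNG: config.sigma_W_young, OLD: config.sigma_W_old}
    m_of = {YOUNG: config.m_young, OLD: config.m_old}
    W_rows = []
    W_lookup: dict[tuple, np.ndarray] = {}
    by_age = individuals.sort_values("birth_year")
    for _, person in by_age.iterrows():
        iid, g = person["id"], int(person["group"]) - 1
        cats = sorted(cats_of[iid]) if spec.split_preferences else [-1]
        for cat in cats:
            mean = mu[g].copy()
            if spec.maternal and person["mother_id"] is not None:
                mkey = (person["mother_id"], OLD)
                if mkey not in W_lookup:
                    mkey = (person["mother_id"], YOUNG)
                Wm = W_lookup[mkey]
                mm = m_of[cat]
                mean = (1 - mm) * mu[g] + mm * Wm
            sd = sig_of[cat] if spec.split_sigma else config.sigma_W
            W = np.zeros(5)
            W[1:] = mean[1:] + sd * rng.standard_normal(4)
            W_lookup[(iid, cat)] = W
            W_rows.append({"individual_id": iid, "age_cat": cat,
                           **{f"W{k + 1}": W[k] for k in range(5)}})
    W_table = pd.DataFrame(W_rows)

    I_RE = {iid: float(rng.normal(0.0, config.sigma_I))
            for iid in individuals["id"]}
    return Population(individuals=individuals, windows=windows, ranks=ranks,
                      covariates=cov, W=W_table, I_RE=I_RE, config=config)


def simulate_events(population: Population, config: SimulationConfig,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw handclasp events under the latent-chooser generative model.

    Returns (events table, latent-truth table).  Dyads are sampled uniformly
    within groups (or with persistent random affinity weights), performer
    roles are randomized per event, the latent situation follows the chooser
    probabilities, and variants are drawn from the chooser's preference
    softmax (the partner matching in situations b/c).
    """
    spec = config.spec
    ind = population.individuals
    J = len(config.group_sizes)
    members = [ind.loc[ind["group"] == j + 1, "id"].to_list() for j in range(J)]
    group_p = np.array([len(m) for m in members], dtype=float)
    group_p /= group_p.sum()
    dyad_weights = []
    for j in range(J):
        n = len(members[j])
        npairs = n * (n - 1) // 2
        if config.partner_affinity is not None:
            w = rng.dirichlet(np.full(npairs, config.partner_affinity))
        else:
            w = np.full(npairs, 1.0 / npairs)
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
        dyad_weights.append((pairs, w))

    cov = {(r.individual_id, r.window_id):
           (np.array([r.age_std, r.sex, r.rank_norm]),
            YOUNG if r.age_cat == "young" else OLD)
           for r in population.covariates.itertuples()}
    windows = population.windows["window_id"].to_list()
    b = np.array([config.beta_age, config.beta_sex, config.beta_rank])
    W_lookup = {(r["individual_id"], int(r["age_cat"])):
                np.array([r[f"W{k}"] for k in range(1, 6)])
                for _, r in population.W.iterrows()}

    p_lookup = {key: preference_probs(Wv) for key, Wv in W_lookup.items()}
    ev_rows, truth_rows = [], []
    for e in range(config.n_events):
        j = int(rng.choice(J, p=group_p))
        pairs, wts = dyad_weights[j]
        if config.partner_affinity is not None:
            a_idx, b_idx = pairs[rng.choice(len(pairs), p=wts)]
        else:
            a_idx, b_idx = pairs[rng.integers(len(pairs))]
        if rng.random() < 0.5:
            a_idx, b_idx = b_idx, a_idx
        id1, id2 = members[j][a_idx], members[j][b_idx]
        w = windows[rng.integers(len(windows))]
        r1 = cov[(id1, w)]
        r2 = cov[(id2, w)]
        I1 = np.exp(population.I_RE[id1] + b @ r1[0])
        I2 = np.exp(population.I_RE[id2] + b @ r2[0])
        pi = chooser_probs(I1, I2, config.beta_a)
        situation = SITUATIONS[rng.choice(3, p=pi)]

        def slot_p(iid, row):
            cat = row[1] if spec.split_preferences else -1
            return p_lookup[(iid, cat)]

        p1 = slot_p(id1, r1)
        p2 = slot_p(id2, r2)
        if situation == "a":
            y1 = 1 + rng.choice(5, p=p1)
            y2 = 1 + rng.choice(5, p=p2)
            chooser = ""
        elif situation == "b":
            y1 = 1 + rng.choice(5, p=p1)
            y2 = y1
            chooser = id1
        else:
            y2 = 1 + rng.choice(5, p=p2)
            y1 = y2
            chooser = id2
        eid = f"e{e + 1:05d}"
        ev_rows.append({"event_id": eid, "window_id": w, "g1_id": id1,
                        "g2_id": id2, "y_g1": int(y1), "y_g2": int(y2)})
        truth_rows.append({"event_id": eid, "situation": situation,
                           "chooser_id": chooser})
    events = pd.DataFrame(ev_rows, columns=["event_id", "window_id", "g1_id",
                                            "g2_id", "y_g1", "y_g2"])
    truth = pd.DataFrame(truth_rows, columns=["event_id", "situation", "chooser_id"])
    return events, truth


def simulate_dataset(config: SimulationConfig, seed: int) -> tuple[Dataset, GroundTruth]:
    """Simulate one full study: population + events + ground-truth ledger."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    population = simulate_population(config, rng)
    events, situations = simulate_events(population, config, rng)
    dataset = Dataset(individuals=population.individuals,
                      windows=population.windows,
                      ranks=population.ranks, events=events)
    truth = GroundTruth(config=config.to_dict(),
                        mu=config.mu_true.tolist(),
                        W=population.W, I_RE=population.I_RE,
                        situations=situations)
    return dataset, truth


def make_recovery_suite(config_grid, replicates: int, seed: int):
    """Reproducible batch of (Dataset, GroundTruth) pairs over a config grid.

    ``config_grid`` is an iterable of :class:`SimulationConfig`; each config
    is replicated ``replicates`` times with distinct child seeds derived from
    the master seed.
    """
    configs = list(config_grid)
    if not configs:
        raise ValueError("config grid is empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(configs) * replicates)
    out = []
    n = 0
    for config in configs:
        for rep in range(replicates):
            child_seed = int(children[n].generate_state(1)[0] % (2 ** 31))
            out.append((config, rep, *simulate_dataset(config, child_seed)))
            n += 1
    return out


def write_suite(suite, path) -> None:
    """Write a recovery suite: one subdirectory per replicate with the CSV
    tables plus the ground-truth ledger (never read by the fitting pipeline)."""
    path = Path(path)
    for n, (config, rep, dataset, truth) in enumerate(suite):
        sub = path / f"rep{n:03d}"
        dataset.to_dir(sub)
        truth.to_json(sub / "ground_truth.json")
        (sub / "config.json").write_text(json.dumps(config.to_dict(), indent=1))


def load_suite(path):
    """Load a written recovery suite back as (config, Dataset, GroundTruth) triples."""
    path = Path(path)
    out = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        config = SimulationConfig.from_dict(json.loads((sub / "config.json").read_text()))
        dataset = Dataset.from_dir(sub)
        truth = GroundTruth.from_json(sub / "ground_truth.json")
        out.append((config, dataset, truth))
    return out
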