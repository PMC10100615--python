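"""Synthetic study-cohort generator with known ground truth.

Emulates a cross-sectional online cohort in which each participant (ego)
completes (a) self-report questionnaires — paranoia (R-GPTS parts A and B),
anxiety (BAI), depression (BDI-II), general / COVID-vaccine / QAnon
conspiracy endorsement, (b) an ego-network survey with tie strengths,
kinship and ego-attributed alter beliefs, and (c) a 160-trial three-armed
probabilistic reversal learning session generated by a hierarchical
Gaussian filter agent.

Latent traits (paranoia, volatility prior, conspiracy mindset) are drawn
from a Gaussian copula whose rank correlations are configurable, then
transformed onto instrument scales by monotone quantile maps — so the
configured correlations are target Spearman coefficients and bounded,
discrete marginals are respected by construction.  Network size is a
shifted Poisson with configurable mean, ego-alter ties are strong with
probability ``p_strong_tie``, and attributed alter beliefs sit around the
ego's own responses with jitter SD ``1 / asb_concordance``.  The true
volatility prior carries a negative paranoia x ties x belief three-way
modulation, and psychopathology carries a protective (negative)
size x assumed-shared-belief interaction; both effect directions are what
the downstream regressions are expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .egonet import (
    ASBWeights,
    Alter,
    EgoNetwork,
    NetworkFeatures,
    compute_features,
)
from .hgf import FilterDivergence, HGFParams, simulate_choices
from .prl_task import RewardSchedule, ScheduleConfig, TaskSession, build_schedule

__all__ = [
    "CohortConfig",
    "EgoRecord",
    "CohortData",
    "ConfigurationError",
    "generate_cohort",
    "generate_ego_network",
    "generate_psychopathology",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration (e.g. non-PSD correlation structure)."""


KINSHIP_PROBS = {
    "parent": 0.15,
    "sibling": 0.15,
    "spouse": 0.10,
    "friend": 0.40,
    "advisor": 0.10,
    "coworker": 0.10,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Correlations are target Spearman (rank) coefficients between the latent
    traits; defaults follow the observed paranoia-volatility (0.24) and
    paranoia-general-conspiracy (0.41) associations, with networks of mean
    size 5 of which 70% of ties are strong and roughly 1 in 6 egos above
    the clinical paranoia cutoff.
    """

    n_egos: int = 372
    seed: int = 0
    rho_paranoia_mu30: float = 0.24
    rho_paranoia_conspiracy: float = 0.41
    rho_mu30_conspiracy: float = 0.17
    mean_network_size: float = 5.0
    p_strong_tie: float = 0.70
    alter_alter_density: float = 0.35
    asb_concordance: float = 1.0
    asb_heterogeneity_sd: float = 1.0  # SD of the per-ego attributed-belief shift
    beta_interaction: float = -0.5     # size x belief on psychopathology
    beta_size: float = -0.3
    beta_belief: float = -0.3
    beta_paranoia: float = 0.5
    psych_noise_sd: float = 1.0
    beta_mu30_threeway: float = -0.3   # paranoia x ties x belief on true mu3_0
    high_paranoia_fraction: float = 62 / 372
    task_config: ScheduleConfig = field(default_factory=ScheduleConfig)
    hgf_population_means: Tuple[float, float] = (-3.0, -0.5)  # (mu3_0, omega2)
    hgf_population_sds: Tuple[float, float] = (0.75, 0.5)
    asb_weights: ASBWeights = field(default_factory=ASBWeights)
    simulate_sessions: bool = True

    def __post_init__(self) -> None:
        if self.n_egos < 2:
            raise ConfigurationError("n_egos must be at least 2")
        for rho in (self.rho_paranoia_mu30, self.rho_paranoia_conspiracy,
                    self.rho_mu30_conspiracy):
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError("correlations must lie in [-1, 1]")
        for p in (self.p_strong_tie, self.alter_alter_density,
                  self.high_paranoia_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.mean_network_size <= 0:
            raise ConfigurationError("mean_network_size must be positive")
        if not self.asb_concordance > 0:
            raise ConfigurationError("asb_concordance must be positive")
        if self.asb_heterogeneity_sd < 0:
            raise ConfigurationError("asb_heterogeneity_sd must be nonnegative")
        np.linalg.cholesky(self.latent_correlation())  # raises if not PD

    def latent_correlation(self) -> np.ndarray:
        """Pearson correlation of the Gaussian copula.

        Target Spearman coefficients are converted via
        ``r = 2 sin(pi * rho_s / 6)`` so that ranks, not raw normals, carry
        the configured association.
        """
        def to_pearson(rho_s: float) -> float:
            return 2.0 * math.sin(math.pi * rho_s / 6.0)

        c = np.array([
            [1.0, to_pearson(self.rho_paranoia_mu30), to_pearson(self.rho_paranoia_conspiracy)],
            [to_pearson(self.rho_paranoia_mu30), 1.0, to_pearson(self.rho_mu30_conspiracy)],
            [to_pearson(self.rho_paranoia_conspiracy), to_pearson(self.rho_mu30_conspiracy), 1.0],
        ])
        try:
            np.linalg.cholesky(c + 1e-12 * np.eye(3))
        except np.linalg.LinAlgError as err:
            raise ConfigurationError("latent correlation matrix is not positive definite") from err
        return c


@dataclass
class EgoRecord:
    """One ego's scored questionnaires and paranoia group."""

    ego_id: str
    rgpts_a_items: Tuple[int, ...]     # 8 items, 0..4
    rgpts_b_items: Tuple[int, ...]     # 10 items, 0..4
    general_items: Tuple[int, ...]     # 5 items, 1..5
    covid_items: Tuple[int, ...]       # 5 items, 1..7
    qanon: int                         # 0..100
    bai: int                           # 0..63
    bdi: int                           # 0..63

    @property
    def rgpts_a(self) -> int:
        return int(sum(self.rgpts_a_items))

    @property
    def rgpts_b(self) -> int:
        return int(sum(self.rgpts_b_items))

    @property
    def rgpts_total(self) -> int:
        return self.rgpts_a + self.rgpts_b

    @property
    def general_score(self) -> int:
        return int(sum(self.general_items))

    @property
    def covid_score(self) -> int:
        return int(sum(self.covid_items))

    @property
    def paranoia_group(self) -> str:
        return "high" if self.rgpts_b >= 11 else "low"


@dataclass
class CohortData:
    """All products of one generation run, sharing ego identifiers."""

    egos: List[EgoRecord]
    networks: List[EgoNetwork]
    sessions: List[TaskSession]
    features: List[NetworkFeatures]
    ground_truth: pd.DataFrame
    config: CohortConfig


def _distribute_total(total: int, n_items: int, per_item_max: int,
                      rng: np.random.Generator) -> Tuple[int, ...]:
    """Spread an integer total over items bounded by ``per_item_max`` each."""
    items = np.zeros(n_items, dtype=int)
    remaining = total
    order = rng.permutation(n_items)
    i = 0
    while remaining > 0:
        idx = order[i % n_items]
        if items[idx] < per_item_max:
            items[idx] += 1
            remaining -= 1
        i += 1
    return tuple(int(v) for v in items)


def _paranoia_b_total(u: float, high_fraction: float) -> int:
    """Monotone quantile map of the paranoia latent onto R-GPTS part B (0-40).

    Egos in the top ``high_fraction`` of the latent land at or above the
    clinical cutoff of 11; everyone else lands below it.
    """
    lo = 1.0 - high_fraction
    if u >= lo and high_fraction > 0:
        frac = (u - lo) / high_fraction
        return min(40, 11 + int(frac * 30))
    frac = u / lo if lo > 0 else 0.0
    return min(10, int(frac * 11))


def generate_ego_network(
    ego_id: str,
    ego_general_items: Sequence[int],
    config: CohortConfig,
    rng: np.random.Generator,
) -> EgoNetwork:
    """Sample one ego's network.

    Size is 1 + Poisson(mean - 1) (at least one alter); each ego-alter tie
    is strong with ``p_strong_tie``; alter-alter pairs (among the first 15)
    exist with ``alter_alter_density`` and are then weak or strong with
    equal probability.  Attributed responses are the ego's own responses
    plus a shared per-ego projection shift (SD ``asb_heterogeneity_sd`` —
    egos differ in how strongly they assume others agree with them) plus
    per-alter discretised Gaussian jitter with SD ``1 / asb_concordance``
    (zero jitter in the infinite-concordance limit), clipped to 1-5.
    """
    size = 1 + int(rng.poisson(max(config.mean_network_size - 1.0, 0.0)))
    if math.isinf(config.asb_concordance):
        # perfect concordance: attributed beliefs coincide with the ego's own
        jitter_sd, shift = 0.0, 0.0
    else:
        jitter_sd = 1.0 / config.asb_concordance
        shift = (rng.normal(0.0, config.asb_heterogeneity_sd)
                 if config.asb_heterogeneity_sd > 0 else 0.0)
    kin_names = list(KINSHIP_PROBS)
    kin_p = np.array([KINSHIP_PROBS[k] for k in kin_names])

    alters = []
    for j in range(size):
        tie = "strong" if rng.random() < config.p_strong_tie else "weak"
        kinship = kin_names[int(rng.choice(len(kin_names), p=kin_p))]
        if jitter_sd > 0:
            jitter = np.rint(rng.normal(0.0, jitter_sd, size=5))
        else:
            jitter = np.zeros(5)
        items = np.clip(np.asarray(ego_general_items) + shift + jitter, 1, 5)
        items = np.rint(items).astype(int)
        alters.append(Alter(alter_id=f"{ego_id}_a{j + 1}",
                            tie=tie, kinship=kinship, items=tuple(items)))

    alter_alter = {}
    capped = [a.alter_id for a in alters[:15]]
    for i in range(len(capped)):
        for j in range(i + 1, len(capped)):
            if rng.random() < config.alter_alter_density:
                strength = "strong" if rng.random() < 0.5 else "weak"
            else:
                strength = "stranger"
            alter_alter[frozenset((capped[i], capped[j]))] = strength
    return EgoNetwork(ego_id=ego_id, alters=alters, alter_alter=alter_alter)


def generate_psychopathology(
    z_paranoia: float,
    size_z: float,
    asb_z: float,
    interaction_z: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> Tuple[int, int, float]:
    """Sample (BAI, BDI) scores and return them with the noiseless predictor.

    The generating linear predictor is
    ``beta_paranoia*z_par + beta_size*size_z + beta_belief*asb_z
    + beta_interaction*interaction_z``, where ``interaction_z`` is the
    within-cohort standardised size x belief product — every generating
    effect is expressed per SD of its term, so the bounded instrument range
    is never saturated by the product's heavy tails.  With a negative
    interaction, larger networks are protective only at high assumed shared
    belief.  Noise is added per instrument before the linear map onto the
    0-63 range, centred mid-scale so the bounds are essentially never hit
    and the linear structure survives.
    """
    eta = (config.beta_paranoia * z_paranoia
           + config.beta_size * size_z
           + config.beta_belief * asb_z
           + config.beta_interaction * interaction_z)
    bai = int(np.clip(round(30 + 5 * (eta + rng.normal(0, config.psych_noise_sd))), 0, 63))
    bdi = int(np.clip(round(30 + 5 * (eta + rng.normal(0, config.psych_noise_sd))), 0, 63))
    return bai, bdi, float(eta)


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate a complete synthetic cohort.

    Fully reproducible from ``config.seed``; all products share ego
    identifiers, and the returned ground-truth table carries the latent
    traits, true perceptual parameters and noiseless psychopathology
    predictor for every ego.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_egos
    z = rng.multivariate_normal(np.zeros(3), config.latent_correlation(), size=n,
                                method="cholesky")
    z_par, z_mu30, z_consp = z[:, 0], z[:, 1], z[:, 2]
    u_par = norm.cdf(z_par)
    u_consp = norm.cdf(z_consp)

    mu30_mean, om2_mean = config.hgf_population_means
    mu30_sd, om2_sd = config.hgf_population_sds
    omega2_true = om2_mean + om2_sd * rng.standard_normal(n)

    schedule = build_schedule(config.task_config)

    egos: List[EgoRecord] = []
    networks: List[EgoNetwork] = []
    features: List[NetworkFeatures] = []
    ego_ids = [f"ego{i + 1:05d}" for i in range(n)]

    # questionnaires + networks first (features feed the mu3_0 modulation)
    for i, ego_id in enumerate(ego_ids):
        b_total = _paranoia_b_total(u_par[i], config.high_paranoia_fraction)
        b_items = _distribute_total(b_total, 10, 4, rng)
        # both subscales are monotone maps of the same paranoia latent, so the
        # configured rank correlations carry through to the A+B total
        a_items = _distribute_total(min(32, int(u_par[i] * 33)), 8, 4, rng)
        gen_total = min(25, 5 + int(u_consp[i] * 21))
        gen_items = tuple(1 + v for v in _distribute_total(gen_total - 5, 5, 4, rng))
        u_cv = norm.cdf(0.8 * z_consp[i] + 0.6 * rng.standard_normal())
        covid_items = tuple(1 + v for v in _distribute_total(min(30, int(u_cv * 31)), 5, 6, rng))
        u_q = norm.cdf(0.7 * z_consp[i] + math.sqrt(1 - 0.49) * rng.standard_normal())
        qanon = min(100, int(u_q * 101))

        net = generate_ego_network(ego_id, gen_items, config, rng)
        networks.append(net)
        features.append(compute_features(net, gen_items, config.asb_weights))
        egos.append(EgoRecord(ego_id=ego_id, rgpts_a_items=a_items,
                              rgpts_b_items=b_items, general_items=gen_items,
                              covid_items=covid_items, qanon=qanon, bai=0, bdi=0))

    size_arr = np.array([f.size for f in features], dtype=float)
    ties_arr = np.array([f.strong_ties for f in features], dtype=float)
    asb_arr = np.array([f.asb for f in features], dtype=float)

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    size_z, ties_z, asb_z = zscore(size_arr), zscore(ties_arr), zscore(asb_arr)

    # Three-way paranoia x ties x belief modulation of the volatility prior.
    # The raw triple product covaries with paranoia (ties and belief are
    # positively related), which would distort the configured marginal
    # paranoia-volatility correlation; residualise it against the intercept
    # and main effects so the modulation carries only unique three-way signal.
    w = z_par * ties_z * asb_z
    design = np.column_stack([np.ones(n), z_par, ties_z, asb_z])
    coef, *_ = np.linalg.lstsq(design, w, rcond=None)
    w_resid = w - design @ coef
    sd_w = w_resid.std()
    if sd_w > 0:
        w_resid = w_resid / sd_w
    mu30_true = (mu30_mean + mu30_sd * z_mu30
                 + config.beta_mu30_threeway * w_resid)

    interaction_z = zscore(size_z * asb_z)

    sessions: List[TaskSession] = []
    psych_eta = np.empty(n)
    for i, ego_id in enumerate(ego_ids):
        bai, bdi, eta = generate_psychopathology(z_par[i], size_z[i], asb_z[i],
                                                 interaction_z[i], config, rng)
        egos[i].bai, egos[i].bdi = bai, bdi
        psych_eta[i] = eta
        if config.simulate_sessions:
            # Very volatile agents (kappa*mu3 + omega2 large) can drive the
            # filter into precision collapse mid-session; such agents are not
            # part of the modelled population. Shrink the offending ego's
            # volatility prior toward the population mean until its dynamics
            # are stable, and record the realised value as the ground truth.
            mu30_i = float(mu30_true[i])
            for _attempt in range(40):
                try:
                    params = HGFParams(mu3_0=mu30_i, omega2=float(omega2_true[i]))
                    sess = simulate_choices(params, schedule, rng,
                                            ego_id=ego_id, frame="social")
                    break
                except (FilterDivergence, OverflowError, ZeroDivisionError):
                    mu30_i = mu30_mean + 0.8 * (mu30_i - mu30_mean)
            else:
                raise ConfigurationError(
                    f"could not stabilise simulated dynamics for {ego_id}"
                )
            mu30_true[i] = mu30_i
            sessions.append(sess)

    ground_truth = pd.DataFrame({
        "ego_id": ego_ids,
        "z_paranoia": z_par,
        "z_mu30": z_mu30,
        "z_conspiracy": z_consp,
        "mu3_0_true": mu30_true,
        "omega2_true": omega2_true,
        "asb_true": asb_arr,
        "psych_eta": psych_eta,
    })
    return CohortData(egos=egos, networks=networks, sessions=sessions,
                      features=features, ground_truth=ground_truth, config=config)


def _cohort_frame(data: CohortData) -> pd.DataFrame:
    rows = []
    for ego in data.egos:
        row: Dict[str, object] = {"ego_id": ego.ego_id}
        for k, v in enumerate(ego.rgpts_a_items, 1):
            row[f"rgpts_a{k}"] = v
        for k, v in enumerate(ego.rgpts_b_items, 1):
            row[f"rgpts_b{k}"] = v
        for k, v in enumerate(ego.general_items, 1):
            row[f"gen{k}"] = v
        for k, v in enumerate(ego.covid_items, 1):
            row[f"covid{k}"] = v
        row.update(rgpts_a=ego.rgpts_a, rgpts_b=ego.rgpts_b,
                   rgpts_total=ego.rgpts_total, general_score=ego.general_score,
                   covid_score=ego.covid_score, qanon=ego.qanon,
                   bai=ego.bai, bdi=ego.bdi, paranoia_group=ego.paranoia_group)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(data: CohortData, outdir) -> Dict[str, Path]:
    """Write the five plain-CSV products of one generation run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["cohort"] = outdir / "cohort.csv"
    _cohort_frame(data).to_csv(paths["cohort"], index=False)

    alter_rows, edge_rows = [], []
    for net in data.networks:
        for a in net.alters:
            alter_rows.append({
                "ego_id": net.ego_id, "alter_id": a.alter_id, "tie": a.tie,
                "kinship": a.kinship,
                **{f"attr_item{k}": v for k, v in enumerate(a.items, 1)},
            })
        for pair, strength in sorted(net.alter_alter.items(), key=lambda kv: sorted(kv[0])):
            a_id, b_id = sorted(pair)
            edge_rows.append({"ego_id": net.ego_id, "node_a": a_id,
                              "node_b": b_id, "strength": strength})
    paths["alters"] = outdir / "networks_alters.csv"
    pd.DataFrame(alter_rows).to_csv(paths["alters"], index=False)
    paths["edges"] = outdir / "networks_edges.csv"
    pd.DataFrame(edge_rows).to_csv(paths["edges"], index=False)

    sess_rows = []
    for sess in data.sessions:
        for t in range(sess.n_trials):
            sess_rows.append({"ego_id": sess.ego_id, "trial": t + 1,
                              "frame": sess.frame,
                              "choice": int(sess.choices[t]),
                              "outcome": int(sess.outcomes[t])})
    paths["sessions"] = outdir / "sessions.csv"
    pd.DataFrame(sess_rows).to_csv(paths["sessions"], index=False)

    paths["ground_truth"] = outdir / "ground_truth.csv"
    data.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths
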