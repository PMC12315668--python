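"""Synthetic three-wave at-risk cohort generator.

Emulates a school-based cohort oversampled for familial psychopathology
risk, followed across three assessment waves (mean ages ~10.2, ~13.5,
~18.2 years).  Five latent constructs evolve under a known sparse
cross-lagged/autoregressive dynamic, and are observed through a
measurement layer with the instruments of the real design: two broad-band
symptom scales (CBCL below age 18, ABCL at or above 18), backward digit
and corsi spans for working memory, and go/no-go summaries (mean correct-go
RT, commission errors out of 25 no-go trials) for inhibitory control.
Dropout is a single monotone event whose probability decreases with
wave-1 internalizing symptoms, calibrated to a target marginal rate.

All cognitive latents are oriented so that higher = better performance;
the measurement layer maps speed to *higher* RT for *lower* latent speed
and accuracy to *more* commission errors for *lower* latent accuracy, so
the downstream inversion step is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "NODES",
    "OBSERVED_VARIABLES",
    "LATENT_COLUMNS",
    "TrueNetwork",
    "MeasurementModel",
    "AttritionModel",
    "GeneratorConfig",
    "PanelDataset",
    "default_true_network",
    "default_config",
    "null_config",
    "single_edge_network",
    "uniform_effect_network",
    "simulate_cohort",
    "simulate_gonogo_summaries",
    "apply_attrition",
    "attrition_rate",
]

#: Latent constructs, in fixed order.  ``inhibition_speed`` and
#: ``inhibition_accuracy`` are oriented higher = better.
NODES = (
    "internalizing",
    "externalizing",
    "working_memory",
    "inhibition_speed",
    "inhibition_accuracy",
)

#: Observed per-wave scores emitted by the measurement layer.
OBSERVED_VARIABLES = (
    "internalizing",
    "externalizing",
    "digit_backward",
    "corsi_backward",
    "go_rt",
    "commission_errors",
)

LATENT_COLUMNS = tuple(f"latent_{n}" for n in NODES)

N_NODES = len(NODES)
N_WAVES = 3
NOGO_TRIALS = 25  # no-go trials in the go/no-go task (75 go + 25 no-go)


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class TrueNetwork:
    """Ground-truth lagged dynamics for the two wave transitions.

    ``lag_matrix_by_wavepair`` holds two square matrices on the standardized
    latent scale; entry ``[i, j]`` is the effect of node *i* at wave *t* on
    node *j* at wave *t+1* (autoregression on the diagonal).  Two matrices
    because the association structure is allowed to change between the
    early-adolescence and middle-adolescence transitions.
    """

    node_names: tuple = NODES
    lag_matrix_by_wavepair: tuple = ()
    innovation_sd: np.ndarray = field(default_factory=lambda: np.full(N_NODES, 0.8))
    age_effects: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.05, 0.05, 0.05])
    )

    def __post_init__(self):
        self.node_names = tuple(self.node_names)
        self.lag_matrix_by_wavepair = tuple(
            np.asarray(m, dtype=float) for m in self.lag_matrix_by_wavepair
        )
        self.innovation_sd = np.asarray(self.innovation_sd, dtype=float)
        self.age_effects = np.asarray(self.age_effects, dtype=float)

    def validate(self) -> None:
        p = len(self.node_names)
        if len(self.lag_matrix_by_wavepair) != N_WAVES - 1:
            raise ValueError("need one lag matrix per wave pair (two)")
        for m in self.lag_matrix_by_wavepair:
            if m.shape != (p, p):
                raise ValueError(f"lag matrix must be {p}x{p}, got {m.shape}")
            rho = np.max(np.abs(np.linalg.eigvals(m)))
            if rho >= 1.0:
                raise ValueError(
                    f"non-stationary lag matrix (spectral radius {rho:.3f} >= 1)"
                )
        if self.innovation_sd.shape != (p,) or np.any(self.innovation_sd < 0):
            raise ValueError("innovation_sd must be a non-negative length-p vector")
        if self.age_effects.shape != (p,):
            raise ValueError("age_effects must be a length-p vector")


@dataclass
class MeasurementModel:
    """Maps latent constructs to observed scores.

    The two span indicators load equally on latent working memory with
    loading ``wm_indicator_loading``; with unit latent variance the implied
    digit/corsi correlation is the squared loading, so the default
    ``sqrt(0.46)`` reproduces the target r = 0.46 exactly in population.
    """

    wm_indicator_cor_target: float = 0.46
    wm_indicator_loading: float | None = None  # derived from target when None
    digit_scale: tuple = (4.5, 1.3)  # raw span units (mean, SD)
    corsi_scale: tuple = (4.8, 1.4)
    rt_scale: tuple = (450.0, 80.0)  # ms
    rt_loading: float = 0.85
    rt_floor: float = 150.0  # ms; physiological lower bound
    error_base_rate: float = 0.18  # commission probability at latent mean
    error_slope: float = 0.5  # logit decrease per latent SD
    symptom_loading: float = 0.9
    # raw broad-band sum scales per instrument: {instrument: {node: (mean, sd)}}
    symptom_scale: dict = field(
        default_factory=lambda: {
            "cbcl": {"internalizing": (8.0, 6.0), "externalizing": (9.0, 7.0)},
            "abcl": {"internalizing": (11.0, 7.0), "externalizing": (10.0, 7.0)},
        }
    )
    # additive latent mean shift per node per wave (z-units): symptoms drift
    # up (internalizing steadily, externalizing peaking at wave 2), cognition
    # improves steadily.
    wave_trends: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 0.15, 0.30],
                [0.0, 0.20, 0.05],
                [0.0, 0.30, 0.60],
                [0.0, 0.30, 0.60],
                [0.0, 0.30, 0.60],
            ]
        )
    )

    def __post_init__(self):
        self.wave_trends = np.asarray(self.wave_trends, dtype=float)

    @property
    def loading(self) -> float:
        if self.wm_indicator_loading is not None:
            return float(self.wm_indicator_loading)
        return float(np.sqrt(self.wm_indicator_cor_target))

    def validate(self) -> None:
        if not 0.0 < self.wm_indicator_cor_target < 1.0:
            raise ValueError("wm_indicator_cor_target must be in (0, 1)")
        if not 0.0 < self.loading <= 1.0:
            raise ValueError("working-memory indicator loading must be in (0, 1]")
        if self.rt_scale[0] <= 0 or self.rt_scale[1] <= 0 or self.rt_floor <= 0:
            raise ValueError("RT scale parameters must be positive")
        if not 0.0 < self.error_base_rate < 1.0:
            raise ValueError("error_base_rate must be in (0, 1)")
        if self.wave_trends.shape != (N_NODES, N_WAVES):
            raise ValueError("wave_trends must be n_nodes x n_waves")


@dataclass
class AttritionModel:
    """Single monotone dropout event with internalizing-dependent hazard.

    Dropout probability is ``logistic(intercept + internalizing_coef * z)``
    with ``z`` the standardized wave-1 internalizing score.  The default
    coefficient is negative: participants with more internalizing symptoms
    at baseline are *less* likely to drop out.  Age, gender, externalizing
    and cognition carry no effect.  ``intercept=None`` requests calibration
    to the configured marginal attrition target.
    """

    intercept: float | None = None
    internalizing_coef: float = -0.3

    def validate(self) -> None:
        if self.internalizing_coef > 0:
            raise ValueError(
                "default attrition model requires a non-positive internalizing "
                "coefficient (higher internalizing -> lower dropout)"
            )


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort."""

    n_participants: int = 2000
    high_risk_fraction: float = 0.6089
    male_fraction: float = 0.53
    age_mean_by_wave: tuple = (10.20, 13.48, 18.20)
    age_sd: float = 0.6
    seed: int = 0
    target_attrition: float = 0.3514
    true_network: TrueNetwork = field(default_factory=lambda: default_true_network())
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    attrition: AttritionModel = field(default_factory=AttritionModel)
    # per-node, per-wave additive latent shift for the high-risk group:
    # symptoms elevated at every wave; cognition lower only at later waves.
    risk_mean_shift: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.5, 0.5, 0.5],
                [0.5, 0.5, 0.5],
                [0.0, 0.0, -0.2],
                [0.0, 0.0, -0.2],
                [0.0, -0.2, -0.2],
            ]
        )
    )

    def __post_init__(self):
        self.risk_mean_shift = np.asarray(self.risk_mean_shift, dtype=float)

    def validate(self) -> None:
        if self.n_participants < 10:
            raise ValueError("n_participants < 10 is degenerate for any analysis")
        if not 0.0 < self.high_risk_fraction < 1.0:
            raise ValueError("high_risk_fraction must be in (0, 1)")
        if not 0.0 <= self.target_attrition < 1.0:
            raise ValueError("target_attrition must be in [0, 1)")
        if self.risk_mean_shift.shape != (N_NODES, N_WAVES):
            raise ValueError("risk_mean_shift must be n_nodes x n_waves")
        self.true_network.validate()
        self.measurement.validate()
        self.attrition.validate()


# ---------------------------------------------------------------------------
# default / special-purpose truth networks


def _idx(name: str) -> int:
    return NODES.index(name)


def default_true_network() -> TrueNetwork:
    """Sparse ground truth mirroring the qualitative association pattern of
    an at-risk adolescent cohort: inhibitory control as a risk factor for
    externalizing problems, symptoms constraining working memory, mutual
    facilitation among executive functions, and a denser, more reciprocal
    structure in the middle-adolescence transition."""
    w12 = np.zeros((N_NODES, N_NODES))
    w23 = np.zeros((N_NODES, N_NODES))
    np.fill_diagonal(w12, 0.4)
    np.fill_diagonal(w23, 0.4)

    i, e, w, s, a = (_idx(n) for n in NODES)
    # wave 1 -> wave 2 (early adolescence)
    w12[a, e] = -0.30  # poor inhibition accuracy -> more externalizing
    w12[s, e] = -0.15
    w12[e, w] = -0.30  # externalizing -> lower working memory
    w12[i, w] = -0.15
    w12[w, a] = 0.30  # working memory <-> inhibition mutualism
    w12[a, w] = 0.15
    w12[w, s] = 0.30
    w12[s, w] = 0.15
    w12[w, e] = 0.15  # weak positive WM -> externalizing

    # wave 2 -> wave 3 (middle adolescence): denser, reciprocal
    w23[a, e] = -0.30
    w23[s, e] = -0.15
    w23[e, a] = -0.30  # externalizing -> worse inhibition (consequence)
    w23[e, s] = -0.15
    w23[i, w] = -0.15
    w23[a, i] = -0.15  # better inhibition -> fewer internalizing
    w23[e, i] = 0.30  # externalizing -> more internalizing
    w23[i, e] = -0.15  # internalizing -> fewer externalizing
    w23[w, s] = 0.30
    w23[s, w] = 0.15
    return TrueNetwork(lag_matrix_by_wavepair=(w12, w23))


def single_edge_network(source: str, target: str, weight: float,
                        ar: float = 0.0) -> TrueNetwork:
    """Truth with a single cross-lagged edge (both wave pairs), optional
    uniform autoregression.  Used for focused recovery checks."""
    m = np.zeros((N_NODES, N_NODES))
    np.fill_diagonal(m, ar)
    m[_idx(source), _idx(target)] = weight
    return TrueNetwork(lag_matrix_by_wavepair=(m, m.copy()))


def uniform_effect_network(effect: float = 0.3, ar: float = 0.4) -> TrueNetwork:
    """Default support pattern with every cross-lagged magnitude set to
    ``effect`` (signs preserved) and autoregression ``ar``."""
    base = default_true_network()
    mats = []
    for m in base.lag_matrix_by_wavepair:
        out = np.zeros_like(m)
        off = ~np.eye(N_NODES, dtype=bool)
        out[off] = np.sign(m[off]) * effect * (m[off] != 0)
        np.fill_diagonal(out, ar)
        mats.append(out)
    return TrueNetwork(lag_matrix_by_wavepair=tuple(mats))


def default_config(n_participants: int = 2000, seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(n_participants=n_participants, seed=seed)


def null_config(n_participants: int = 500, seed: int = 0) -> GeneratorConfig:
    """Pure-noise cohort: no lagged effects, no age effects, no group mean
    shifts, no wave trends, no attrition.  Any cross-wave association in the
    observed data is sampling noise."""
    zero = np.zeros((N_NODES, N_NODES))
    truth = TrueNetwork(
        lag_matrix_by_wavepair=(zero, zero.copy()),
        innovation_sd=np.ones(N_NODES),
        age_effects=np.zeros(N_NODES),
    )
    meas = MeasurementModel(wave_trends=np.zeros((N_NODES, N_WAVES)))
    return GeneratorConfig(
        n_participants=n_participants,
        seed=seed,
        true_network=truth,
        measurement=meas,
        risk_mean_shift=np.zeros((N_NODES, N_WAVES)),
        target_attrition=0.0,
    )


# ---------------------------------------------------------------------------
# the panel container


@dataclass
class PanelDataset:
    """One row per participant x wave, wide variable columns.

    Columns: participant_id, wave (1-3), group, age, gender, instrument,
    the observed variables, and the generating latents (``latent_*``).
    Missing cells are NaN; a dropped-out participant is missing every wave
    variable from the dropout wave onward.
    """

    table: pd.DataFrame

    COLUMNS = (
        ("participant_id", "wave", "group", "age", "gender", "instrument")
        + OBSERVED_VARIABLES
        + LATENT_COLUMNS
    )

    def __post_init__(self):
        missing = [c for c in ("participant_id", "wave") if c not in self.table]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        dup = self.table.duplicated(subset=["participant_id", "wave"])
        if dup.any():
            rows = self.table.loc[dup, ["participant_id", "wave"]].head(5)
            raise ValueError(
                f"duplicate (participant, wave) records, e.g.:\n{rows}"
            )
        self.table = (
            self.table.sort_values(["participant_id", "wave"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_participants(self) -> int:
        return self.table["participant_id"].nunique()

    @property
    def waves(self) -> list:
        return sorted(self.table["wave"].unique())

    def wave(self, w: int) -> pd.DataFrame:
        """Rows of one wave, indexed by participant_id."""
        out = self.table[self.table["wave"] == w]
        return out.set_index("participant_id")

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.table.copy())

    def equals(self, other: "PanelDataset") -> bool:
        return self.table.equals(other.table)


# ---------------------------------------------------------------------------
# simulation


def _simulate_latents(rng: np.random.Generator, config: GeneratorConfig,
                      high_risk: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Latent scores, shape (n, n_nodes, n_waves).

    Recursion per participant i, node vector z:
        z[1]   = eps1 + trend[1] + shift[1]*hr
        z[t+1] = L_t' z[t] + age_effects*(age[t+1]-mean_age[t+1])
                 + innovation_sd*eps[t+1] + trend[t+1] + shift[t+1]*hr

    Draw order (fixed, documents determinism): wave-1 innovations as one
    (n, p) block, then per transition one (n, p) innovation block.
    """
    n = config.n_participants
    tn = config.true_network
    trends = config.measurement.wave_trends
    shifts = config.risk_mean_shift
    hr = high_risk.astype(float)[:, None]

    z = np.empty((n, N_NODES, N_WAVES))
    z[:, :, 0] = rng.standard_normal((n, N_NODES)) + trends[:, 0] + shifts[:, 0] * hr
    for t in range(N_WAVES - 1):
        lag = tn.lag_matrix_by_wavepair[t]
        eps = rng.standard_normal((n, N_NODES))
        age_dev = ages[:, t + 1] - config.age_mean_by_wave[t + 1]
        z[:, :, t + 1] = (
            z[:, :, t] @ lag
            + tn.age_effects * age_dev[:, None]
            + tn.innovation_sd * eps
            + trends[:, t + 1]
            + shifts[:, t + 1] * hr
        )
    return z


def simulate_gonogo_summaries(latent_speed, latent_accuracy,
                              measurement: MeasurementModel, seed=None):
    """Observed go/no-go summaries from latent inhibition scores.

    RT (ms) decreases linearly in latent speed plus Gaussian noise, floored
    at a physiological minimum; commission errors are Binomial(25, p) with
    p decreasing in latent accuracy on the logit scale.

    ``seed`` may be an int or an already-constructed Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    speed = np.asarray(latent_speed, dtype=float)
    acc = np.asarray(latent_accuracy, dtype=float)
    m, s = measurement.rt_scale
    lo = measurement.rt_loading
    rt = m + s * (-lo * speed + np.sqrt(1.0 - lo**2) * rng.standard_normal(speed.shape))
    rt = np.maximum(rt, measurement.rt_floor)
    p = expit(logit(measurement.error_base_rate) - measurement.error_slope * acc)
    errors = rng.binomial(NOGO_TRIALS, p).astype(float)
    return rt, errors


def simulate_cohort(config: GeneratorConfig) -> PanelDataset:
    """Generate a complete (pre-attrition) synthetic cohort.

    Deterministic under ``config.seed``: one Generator consumed in a fixed
    order (group, gender, age offsets, latents wave-by-wave, then the
    measurement layer wave-by-wave).
    """
    config.validate()
    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    high_risk = rng.random(n) < config.high_risk_fraction
    gender = (rng.random(n) < config.male_fraction).astype(int)
    age_offset = rng.normal(0.0, config.age_sd, n)
    ages = np.array(config.age_mean_by_wave)[None, :] + age_offset[:, None]

    z = _simulate_latents(rng, config, high_risk, ages)

    meas = config.measurement
    a = meas.loading
    b = float(np.sqrt(1.0 - a * a))
    i_int, i_ext, i_wm, i_sp, i_ac = (_idx(nm) for nm in NODES)

    ids = np.array([f"P{k:06d}" for k in range(n)])
    frames = []
    for t in range(N_WAVES):
        wave = t + 1
        wm = z[:, i_wm, t]
        digit_z = a * wm + b * rng.standard_normal(n)
        corsi_z = a * wm + b * rng.standard_normal(n)
        digit = meas.digit_scale[0] + meas.digit_scale[1] * digit_z
        corsi = meas.corsi_scale[0] + meas.corsi_scale[1] * corsi_z

        rt, errors = simulate_gonogo_summaries(z[:, i_sp, t], z[:, i_ac, t], meas, rng)

        instrument = np.where((wave == 3) & (ages[:, t] >= 18.0), "abcl", "cbcl")
        sl = meas.symptom_loading
        sb = float(np.sqrt(1.0 - sl * sl))
        sym = {}
        for node, latent_i in (("internalizing", i_int), ("externalizing", i_ext)):
            score_z = sl * z[:, latent_i, t] + sb * rng.standard_normal(n)
            raw = np.empty(n)
            for inst in ("cbcl", "abcl"):
                mask = instrument == inst
                mu, sd = meas.symptom_scale[inst][node]
                raw[mask] = mu + sd * score_z[mask]
            sym[node] = raw

        frame = pd.DataFrame(
            {
                "participant_id": ids,
                "wave": wave,
                "group": np.where(high_risk, "high_risk", "community"),
                "age": ages[:, t],
                "gender": gender,
                "instrument": instrument,
                "internalizing": sym["internalizing"],
                "externalizing": sym["externalizing"],
                "digit_backward": digit,
                "corsi_backward": corsi,
                "go_rt": rt,
                "commission_errors": errors,
            }
        )
        for j, nm in enumerate(NODES):
            frame[f"latent_{nm}"] = z[:, j, t]
        frames.append(frame)

    return PanelDataset(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# attrition


def _calibrate_intercept(z: np.ndarray, coef: float, target: float) -> float:
    """Solve for the logit intercept giving marginal dropout ``target``."""
    if not 0.0 < target < 1.0:
        raise ValueError("calibration target must be in (0, 1)")

    def gap(a):
        return float(np.mean(expit(a + coef * z))) - target

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - unreachable for target in (0,1)
        raise ValueError("target attrition unreachable for the given coefficient")
    return brentq(gap, lo, hi, xtol=1e-12)


def apply_attrition(data: PanelDataset, model: AttritionModel, seed: int,
                    target_attrition: float = 0.3514) -> PanelDataset:
    """Mark dropped participants missing from their dropout wave onward.

    Each participant drops with probability
    ``logistic(intercept + internalizing_coef * z(internalizing at wave 1))``;
    when ``model.intercept`` is None the intercept is solved so the marginal
    rate equals ``target_attrition``.  The dropout wave is 2 or 3 with equal
    probability and missingness is monotone.
    """
    model.validate()
    if target_attrition == 0.0:
        return data.copy()
    if not 0.0 < target_attrition < 1.0:
        raise ValueError("target_attrition must be in [0, 1)")

    w1 = data.wave(1)["internalizing"]
    if w1.isna().any():
        raise ValueError("wave-1 internalizing must be observed for everyone")
    z = ((w1 - w1.mean()) / w1.std(ddof=1)).to_numpy()

    intercept = model.intercept
    if intercept is None:
        intercept = _calibrate_intercept(z, model.internalizing_coef, target_attrition)

    rng = np.random.default_rng(seed)
    p = expit(intercept + model.internalizing_coef * z)
    dropped = rng.random(len(p)) < p
    drop_wave = rng.integers(2, 4, size=len(p))  # 2 or 3, equal probability

    ids = w1.index.to_numpy()
    drop_map = dict(zip(ids[dropped], drop_wave[dropped]))

    table = data.table.copy()
    wave_cols = list(OBSERVED_VARIABLES) + list(LATENT_COLUMNS) + ["age"]
    first_missing = table["participant_id"].map(drop_map)
    mask = first_missing.notna() & (table["wave"] >= first_missing)
    table.loc[mask, wave_cols] = np.nan
    table.loc[mask, "instrument"] = np.nan
    return PanelDataset(table)


def attrition_rate(data: PanelDataset) -> float:
    """Fraction of wave-1 participants missing internalizing at wave 2 or 3."""
    w1 = set(data.wave(1).index)
    missing = set()
    for w in (2, 3):
        sub = data.wave(w)["internalizing"]
        missing |= set(sub.index[sub.isna()])
    return len(missing & w1) / len(w1)
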