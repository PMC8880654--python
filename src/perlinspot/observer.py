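"""Synthetic observers for the spot-the-difference task.

Simulates cohorts whose trial outcomes reproduce the group-level behaviour
reported for the four presentation formats: per-condition total-miss rates,
true change-blindness (timeout) rates, hit detection-time medians, and the
cross-condition correlation structure of miss counts (horizontal and
200 ms-ISI misses co-vary most strongly).

Outcome model per trial, given a participant's per-condition rates:

1. with probability ``p_cb`` (scaled by a per-strength difficulty
   multiplier) the trial times out after 30 s — "true" change blindness;
2. otherwise the observer reports detection at a time drawn from a
   truncated lognormal, and marks either a uniformly random location
   (probability ``p_guess`` — a guess or misperceived location) or the
   true target centre plus isotropic Gaussian jitter.

Individual differences follow a latent-factor model: a general detection
factor loads on the horizontal, vertical and 200 ms-ISI conditions, and a
second factor loads on the vertical condition alone, yielding the reported
ordering of between-condition miss correlations.  Population logits are
numerically de-biased so cohort means match the configured targets despite
the nonlinear logistic mixing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize

from .stimuli import FORMAT_NAMES, StimulusPair, PresentationFormat, standard_formats

_AOI_RADIUS_CM = 1.0
_DEFAULT_P_CHANCE = 2.0 * np.pi * _AOI_RADIUS_CM**2 / 8.7**2  # mirrors the scoring default


def _per_condition(values) -> dict[str, float]:
    return dict(zip(FORMAT_NAMES, values))


@dataclass
class ObserverParams:
    """Population-level observer parameters, keyed by condition name.

    ``m_total`` are the target group-mean total-miss probabilities and
    ``p_cb`` the timeout (change-blindness) probabilities; the residual
    AOI-miss mass is produced by guessed marks at a rate recovered by
    :func:`calibrate_guess_rate`.  ``loading`` and ``eta`` set the latent
    factor structure of individual differences; ``strength_multiplier``
    applies a mild monotone difficulty effect of target amplitude.
    """

    p_cb: dict[str, float] = field(
        default_factory=lambda: _per_condition((0.07, 0.06, 0.024, 0.0)))
    m_total: dict[str, float] = field(
        default_factory=lambda: _per_condition((0.23, 0.43, 0.19, 0.003)))
    median_s: dict[str, float] = field(
        default_factory=lambda: _per_condition((9.0, 9.0, 6.0, 1.5)))
    sd_log: float = 0.5
    sigma_mark_cm: float = 0.3
    loading: dict[str, float] = field(
        default_factory=lambda: _per_condition((1.0, 0.8, 1.0, 0.0)))
    eta: float = 0.9
    strength_multiplier: dict[int, float] = field(
        default_factory=lambda: {40: 1.15, 50: 1.0, 60: 0.85})
    p_chance_hit: float = _DEFAULT_P_CHANCE
    seed: int = 0

    def __post_init__(self):
        for c in FORMAT_NAMES:
            if not 0.0 <= self.p_cb[c] <= 1.0 or not 0.0 <= self.m_total[c] <= 1.0:
                raise ValueError(f"probabilities for {c!r} must lie in [0, 1]")
            if self.m_total[c] < self.p_cb[c]:
                raise ValueError(f"m_total < p_cb for condition {c!r}")
            if not self.median_s[c] < 30.0:
                raise ValueError(f"median detection time for {c!r} must be < 30 s")


@dataclass
class TrialRecord:
    """One trial of one participant in one condition.

    Undetected trials (timeouts) carry no detection time and no mark.
    """

    participant_id: str
    condition: str
    pair_id: str
    strength: int
    detected: bool
    detection_time_s: float | None
    mark_x_cm: float | None
    mark_y_cm: float | None
    target_x_cm: float
    target_y_cm: float


def validate_record(rec: TrialRecord, row: int | None = None) -> None:
    """Enforce the trial-record invariants, naming the offending row."""
    where = "" if row is None else f" (row {row})"
    if rec.condition not in FORMAT_NAMES:
        raise ValueError(f"unknown condition {rec.condition!r}{where}")
    if rec.detected:
        if rec.detection_time_s is None or not 0.0 < rec.detection_time_s <= 30.0:
            raise ValueError(f"detected trial needs a time in (0, 30]{where}")
        if rec.mark_x_cm is None or rec.mark_y_cm is None:
            raise ValueError(f"detected trial needs mark coordinates{where}")
    else:
        if rec.detection_time_s is not None or rec.mark_x_cm is not None or rec.mark_y_cm is not None:
            raise ValueError(f"undetected trial must carry no time and no mark{where}")


# ---------------------------------------------------------------------------
# calibration


def calibrate_guess_rate(m_total: float, p_cb: float, p_chance_hit: float) -> float:
    """Invert the outcome mixture for the guessed-mark probability.

    Solves ``m_total = p_cb + (1 - p_cb) * p_guess * (1 - p_chance_hit)``
    so that simulated total-miss rates land on the configured targets
    (a uniformly guessed mark still hits the scoring region with
    probability ``p_chance_hit``).  Clamped to [0, 1] with a warning.
    """
    if not 0.0 <= m_total <= 1.0 or not 0.0 <= p_cb <= 1.0 or not 0.0 <= p_chance_hit < 1.0:
        raise ValueError("probabilities out of range")
    if m_total < p_cb:
        raise ValueError(f"m_total={m_total} below p_cb={p_cb}: mixture unsolvable")
    if p_cb == 1.0:
        return 0.0
    p = (m_total - p_cb) / ((1.0 - p_cb) * (1.0 - p_chance_hit))
    if p > 1.0:
        warnings.warn(f"guess rate {p:.4f} clamped to 1.0", stacklevel=2)
        p = 1.0
    return p


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(2.0 * math.pi)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@lru_cache(maxsize=256)
def _debiased_logit(p_target: float, latent_sd: float) -> float:
    """Population logit mu with E[expit(mu + latent_sd * Z)] = p_target.

    Gauss–Hermite quadrature plus root-finding; without this correction
    the logistic-normal mixture inflates small population rates.
    """
    if latent_sd == 0.0:
        return math.log(p_target / (1.0 - p_target))

    def gap(mu):
        return float(np.sum(_GH_WEIGHTS * _expit(mu + latent_sd * _GH_NODES))) - p_target

    return float(optimize.brentq(gap, -60.0, 60.0, xtol=1e-12))


@dataclass
class ParticipantRates:
    """Per-condition trial-level probabilities for one simulated observer."""

    participant_id: str
    p_cb: dict[str, float]
    p_guess: dict[str, float]
    general_factor: float
    vertical_factor: float


def sample_participant(
    params: ObserverParams,
    rng: np.random.Generator,
    participant_id: str = "p00",
) -> ParticipantRates:
    """Draw one observer's per-condition timeout and guess probabilities.

    A general factor g ~ N(0,1) shifts the guess-rate logit of every loaded
    condition; an independent factor s ~ N(0,1) additionally shifts the
    vertical condition.  Timeout probabilities scale proportionally with
    the guess rate, so poor searchers both time out and guess more.
    """
    g = rng.standard_normal()
    s = rng.standard_normal()
    p_cb_i: dict[str, float] = {}
    p_guess_i: dict[str, float] = {}
    for c in FORMAT_NAMES:
        target = calibrate_guess_rate(params.m_total[c], params.p_cb[c], params.p_chance_hit)
        lam = params.loading[c]
        eta = params.eta if c == "vertical" else 0.0
        sd = math.hypot(lam, eta)
        if target <= 0.0 or target >= 1.0 or sd == 0.0:
            pg = target
        else:
            mu = _debiased_logit(target, sd)
            pg = float(_expit(mu + lam * g + eta * s))
        p_guess_i[c] = pg
        if target > 0.0:
            p_cb_i[c] = min(1.0, params.p_cb[c] * pg / target)
        else:
            p_cb_i[c] = params.p_cb[c]
    return ParticipantRates(
        participant_id=participant_id,
        p_cb=p_cb_i, p_guess=p_guess_i,
        general_factor=float(g), vertical_factor=float(s),
    )


# ---------------------------------------------------------------------------
# trial and experiment simulation


def _truncated_lognormal(median: float, sd_log: float, limit: float,
                         rng: np.random.Generator) -> float:
    mu = math.log(median)
    for _ in range(1000):
        t = rng.lognormal(mu, sd_log)
        if t <= limit:
            return t
    return limit  # pragma: no cover - P(reach) astronomically small


def simulate_trial(
    rates: ParticipantRates,
    pair: StimulusPair,
    fmt: PresentationFormat,
    rng: np.random.Generator,
    params: ObserverParams,
) -> TrialRecord:
    """Generate one trial outcome for a participant/pair/format triple."""
    c = fmt.name
    mult = params.strength_multiplier.get(pair.strength, 1.0)
    p_timeout = min(1.0, rates.p_cb[c] * mult)
    tx, ty = pair.target.center_x_cm, pair.target.center_y_cm
    side = pair.base.side_cm

    if rng.random() < p_timeout:
        return TrialRecord(rates.participant_id, c, pair.pair_id, pair.strength,
                           detected=False, detection_time_s=None,
                           mark_x_cm=None, mark_y_cm=None,
                           target_x_cm=tx, target_y_cm=ty)

    t = _truncated_lognormal(params.median_s[c], params.sd_log, fmt.time_limit_s, rng)
    if rng.random() < rates.p_guess[c]:
        mx = rng.uniform(0.0, side)
        my = rng.uniform(0.0, side)
    else:
        mx = min(max(tx + rng.normal(0.0, params.sigma_mark_cm), 0.0), side)
        my = min(max(ty + rng.normal(0.0, params.sigma_mark_cm), 0.0), side)
    return TrialRecord(rates.participant_id, c, pair.pair_id, pair.strength,
                       detected=True, detection_time_s=float(t),
                       mark_x_cm=float(mx), mark_y_cm=float(my),
                       target_x_cm=tx, target_y_cm=ty)


def simulate_experiment(
    params: ObserverParams,
    stimulus_set: list[StimulusPair],
    n_participants: int = 30,
    formats: dict[str, PresentationFormat] | None = None,
) -> list[TrialRecord]:
    """Simulate a full cohort: every participant sees every pair in every format.

    Trial order is randomized within each (participant, format) block.
    Deterministic for a fixed ``params.seed``.
    """
    if not stimulus_set:
        raise ValueError("stimulus set is empty")
    if formats is None:
        formats = standard_formats()
    rng = np.random.default_rng(params.seed)
    records: list[TrialRecord] = []
    for p in range(n_participants):
        pid = f"p{p:02d}"
        rates = sample_participant(params, rng, participant_id=pid)
        for fmt in formats.values():
            order = rng.permutation(len(stimulus_set))
            for idx in order:
                records.append(simulate_trial(rates, stimulus_set[idx], fmt, rng, params))
    return records


def null_params(miss: float = 0.2, p_cb: float = 0.05, seed: int = 0) -> ObserverParams:
    """Exchangeable-condition parameters with no individual differences.

    Every condition shares one miss rate and all latent loadings are zero,
    so between-condition differences arise from sampling noise alone —
    the null configuration for type-I-error calibration of per-individual
    condition comparisons.
    """
    same = _per_condition((miss,) * 4)
    cb = _per_condition((p_cb,) * 4)
    zero = _per_condition((0.0,) * 4)
    return ObserverParams(p_cb=cb, m_total=same, loading=zero, eta=0.0,
                          strength_multiplier={40: 1.0, 50: 1.0, 60: 1.0},
                          seed=seed)
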