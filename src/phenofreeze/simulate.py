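"""Synthetic threat-conditioning cohorts with known ground truth.

Generates per-animal freezing sessions with the statistical structure
the analysis pipeline assumes: a mixture of phasic (fast-decay) and
sustained (slow-decay) responders, multiplicative lognormal noise around
the exponential decay curve (so the log-linear fit is the correctly
specified estimator), session-wise extinction of the CS-onset level,
Bernoulli phenotype shifts between the first two retrievals, a female
boost of sustained-phase freezing, and anxiety-test metrics whose means
depend on the true phenotype.  Every draw comes from one seeded
generator, so identical config + seed gives byte-identical output.

The ground-truth table (true phenotype and curve parameters per
animal-session) is returned separately and never mixed into the
analysis-facing tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .session import (FreezingSession, N_BINS, SESSIONS, SUSTAINED_BINS,
                      sessions_to_frame)

#: minimum CS-onset level after extinction decrements, percent
_Y0_FLOOR = 1.0

#: anxiety metrics: (sustained-group mean, phasic-group mean, sd).
#: Directions follow the phenotype contrast (sustained animals avoid:
#: more periphery/corner time, fewer object approaches, less open-arm
#: and light time); magnitudes are free generator choices.
DEFAULT_METRIC_EFFECTS: dict[str, tuple[float, float, float]] = {
    "oft_periphery_s": (380.0, 280.0, 40.0),
    "oft_corner_s": (60.0, 30.0, 12.0),
    "noe_approaches": (8.0, 15.0, 4.0),
    "epm_open_s": (45.0, 90.0, 20.0),
    "epm_open_ends_s": (15.0, 35.0, 10.0),
    "ldt_light_s": (110.0, 160.0, 35.0),
}


@dataclass
class SyntheticConfig:
    """Generator parameters for a synthetic conditioning cohort.

    Decay-rate and intercept distributions are (mean, sd) of normal
    draws; freezing percentages are clamped to [0, 100] after noise.
    ``p_shift_s_to_p`` / ``p_shift_p_to_s`` are the per-animal Bernoulli
    probabilities of switching phenotype between MR1 and MR2, defaulting
    inside the observed shifter ranges (27.5-34% and 15.8-17.5%).
    """

    n_per_sex: int = 48
    sessions: tuple[str, ...] = ("MR1", "MR2")
    p_sustained: float = 0.5
    b_phasic: tuple[float, float] = (0.25, 0.05)
    b_sustained: tuple[float, float] = (0.02, 0.02)
    y0: tuple[float, float] = (85.0, 8.0)
    sigma_log: float = 0.25
    baseline: tuple[float, float] = (8.0, 4.0)
    female_sustained_boost: float = 10.0
    phasic_extinction_per_session: float = 6.0
    p_shift_s_to_p: float = 0.30
    p_shift_p_to_s: float = 0.17
    metric_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_EFFECTS))
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_per_sex < 0:
            problems.append(f"n_per_sex must be >= 0, got {self.n_per_sex}")
        for s in self.sessions:
            if s not in SESSIONS:
                problems.append(f"unknown session label {s!r}")
        for name in ("p_sustained", "p_shift_s_to_p", "p_shift_p_to_s"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        for name in ("b_phasic", "b_sustained", "y0", "baseline"):
            _, sd = getattr(self, name)
            if sd < 0:
                problems.append(f"{name} sd must be >= 0, got {sd}")
        if self.sigma_log < 0:
            problems.append(f"sigma_log must be >= 0, got {self.sigma_log}")
        if self.phasic_extinction_per_session < 0:
            problems.append("phasic_extinction_per_session must be >= 0")
        if self.y0[0] <= 0:
            problems.append(f"y0 mean must be > 0, got {self.y0[0]}")
        for m, (_, _, sd) in self.metric_effects.items():
            if sd < 0:
                problems.append(f"metric {m!r} sd must be >= 0, got {sd}")
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sessions"] = list(data["sessions"])
        data["metric_effects"] = {k: list(v) for k, v in data["metric_effects"].items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "sessions" in data:
            data["sessions"] = tuple(data["sessions"])
        for key in ("b_phasic", "b_sustained", "y0", "baseline"):
            if key in data:
                data[key] = tuple(data[key])
        if "metric_effects" in data:
            data["metric_effects"] = {k: tuple(v) for k, v in data["metric_effects"].items()}
        return cls(**data)


def _retrieval_index(session: str) -> int | None:
    return int(session.removeprefix("MR")) if session.startswith("MR") else None


def generate_session(animal_id: str, sex: str, session: str, y0: float, b: float,
                     config: SyntheticConfig, rng: np.random.Generator) -> FreezingSession:
    """One 24-bin session for an animal with true curve (y0, b).

    ``y0`` must already include any extinction decrement for this
    retrieval.  The Adaptation session has no CS: all bins come from the
    baseline distribution.
    """
    base_mu, base_sd = config.baseline
    bins = np.clip(rng.normal(base_mu, base_sd, size=N_BINS), 0.0, 100.0)
    if _retrieval_index(session) is not None:
        t = np.arange(12, dtype=float)
        cs = y0 * np.exp(-b * t)
        if config.sigma_log > 0:
            cs = cs * np.exp(rng.normal(0.0, config.sigma_log, size=12))
        if sex == "female" and config.female_sustained_boost != 0.0:
            cs[SUSTAINED_BINS[0] - 13:] += config.female_sustained_boost
        bins[12:] = np.clip(cs, 0.0, 100.0)
    return FreezingSession(animal_id=animal_id, sex=sex, session=session,
                           bins=tuple(bins))


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: (sessions table, metrics table, ground truth).

    Per animal: sex, an MR1 phenotype drawn with probability
    ``p_sustained``, per-phenotype decay rate, and a CS-onset level.
    Between MR1 and MR2 the phenotype switches with the configured shift
    probability (a fresh decay rate is drawn for the new phenotype); the
    CS-onset level drops by ``phasic_extinction_per_session`` percent
    per successive retrieval, clamped at 1%.  Metrics are drawn per true
    MR1 phenotype.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sessions_rows: list[FreezingSession] = []
    truth_rows: list[dict] = []
    metric_rows: list[dict] = []

    counter = 0
    for sex in ("female", "male"):
        for _ in range(config.n_per_sex):
            counter += 1
            animal_id = f"{'F' if sex == 'female' else 'M'}{counter:03d}"
            phen_mr1 = "sustained" if rng.random() < config.p_sustained else "phasic"
            b_dist = config.b_sustained if phen_mr1 == "sustained" else config.b_phasic
            b_mr1 = float(rng.normal(*b_dist))
            y0_base = float(np.clip(rng.normal(*config.y0), _Y0_FLOOR, 100.0))

            p_shift = (config.p_shift_s_to_p if phen_mr1 == "sustained"
                       else config.p_shift_p_to_s)
            shifted = bool(rng.random() < p_shift)
            if shifted:
                phen_post = "phasic" if phen_mr1 == "sustained" else "sustained"
                post_dist = (config.b_sustained if phen_post == "sustained"
                             else config.b_phasic)
                b_post = float(rng.normal(*post_dist))
            else:
                phen_post, b_post = phen_mr1, b_mr1

            for sess in config.sessions:
                r = _retrieval_index(sess)
                if r is None:
                    phen, b, y0_s = phen_mr1, b_mr1, y0_base
                else:
                    phen = phen_mr1 if r <= 1 else phen_post
                    b = b_mr1 if r <= 1 else b_post
                    y0_s = max(y0_base - config.phasic_extinction_per_session * (r - 1),
                               _Y0_FLOOR)
                sessions_rows.append(
                    generate_session(animal_id, sex, sess, y0_s, b, config, rng))
                truth_rows.append({"animal_id": animal_id, "sex": sex, "session": sess,
                                   "phenotype": phen, "y0": y0_s, "b": b})

            row: dict = {"animal_id": animal_id}
            for metric, (mu_s, mu_p, sd) in config.metric_effects.items():
                mu = mu_s if phen_mr1 == "sustained" else mu_p
                row[metric] = float(max(rng.normal(mu, sd), 0.0))
            metric_rows.append(row)

    sessions_df = sessions_to_frame(sessions_rows)
    metrics_df = pd.DataFrame(
        metric_rows, columns=["animal_id", *config.metric_effects.keys()])
    truth_df = pd.DataFrame(
        truth_rows, columns=["animal_id", "sex", "session", "phenotype", "y0", "b"])
    return sessions_df, metrics_df, truth_df
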