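"""Synthetic SHARE-like cohorts: sequences from templates, covariates, outcomes.

Real harmonized life-history data are access-restricted, so every pipeline
stage is exercised on generated cohorts instead. A cohort is built in three
layers, each driven by an independent substream of one global integer seed:

1. *Sequences*: each subject copies a trajectory template (a piecewise-
   constant state path tiling ages 16-64) for their cluster, then each age is
   independently corrupted with probability ``noise_rate``, replacing the
   state by a uniformly random *different* state. This i.i.d. corruption is
   the simplest noise consistent with a clustered panel; it does not emulate
   the serially correlated reporting errors or country heterogeneity of real
   life calendars.
2. *Covariates*: baseline age, birth year (spanning all three crisis
   cohorts), BMI, smoking, chronic-condition count, activity and attrition
   drawn from simple parametric distributions whose defaults echo the
   published cohort's baseline table.
3. *Outcomes*: independent Bernoulli draws with
   P(cancer) = logistic(intercept + log-OR[cluster] + covariate terms),
   the same generating family the association model fits.

Seed splitting: stream ``j`` of seed ``s`` is
``numpy.random.default_rng(numpy.random.SeedSequence(s, spawn_key=(j,)))``
with j = 0 sequences, 1 covariates, 2 outcomes — so regenerating any one
layer is bit-identical regardless of which other layers were drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .life_calendar import (
    DEFAULT_ALPHABET,
    DEFAULT_END_AGE,
    DEFAULT_START_AGE,
    SequencePanel,
    StateAlphabet,
    StateSequence,
)

_STREAM_PANEL, _STREAM_COVARIATES, _STREAM_OUTCOMES = 0, 1, 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(stream,)))


@dataclass(frozen=True)
class TrajectoryTemplate:
    """A piecewise-constant state path: (age_from, age_to, state) segments
    tiling the half-open span [16, 65)."""

    label: str
    segments: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        if not segs:
            raise ValueError("template needs at least one segment")
        for (a0, a1, _), (b0, _, _) in zip(segs, segs[1:]):
            if a1 != b0:
                raise ValueError(
                    f"template {self.label!r}: segments must be contiguous "
                    f"({a1} != {b0})"
                )

    @property
    def span(self) -> tuple[int, int]:
        segs = sorted(self.segments)
        return segs[0][0], segs[-1][1]

    def expand(self) -> np.ndarray:
        start, end = self.span
        states = np.empty(end - start, dtype=np.int64)
        for a0, a1, code in self.segments:
            states[a0 - start : a1 - start] = code
        return states


# Transition ages are fixed module constants chosen to echo the described
# trajectory shapes (e.g. a mid-working-life full-time -> home/family move at
# age 33); they are configuration for the generator, not estimates from data.
_FEMALE_TEMPLATES = (
    TrajectoryTemplate("Mainly full-time", ((16, 20, 7), (20, 65, 1))),
    TrajectoryTemplate("Mainly home/family", ((16, 17, 7), (17, 65, 5))),
    TrajectoryTemplate(
        "Mainly full-time to home/family", ((16, 20, 7), (20, 33, 1), (33, 65, 5))
    ),
    TrajectoryTemplate("Mainly self-employment", ((16, 19, 7), (19, 65, 3))),
    TrajectoryTemplate(
        "Full-time or home/family to part time",
        ((16, 19, 7), (19, 27, 1), (27, 33, 5), (33, 65, 2)),
    ),
    TrajectoryTemplate(
        "Home/family to full-time", ((16, 18, 7), (18, 40, 5), (40, 65, 1))
    ),
    TrajectoryTemplate("Mainly unemployment", ((16, 18, 7), (18, 65, 4))),
    TrajectoryTemplate("Other", ((16, 19, 7), (19, 65, 8))),
)

_MALE_TEMPLATES = (
    TrajectoryTemplate("Mainly full-time", ((16, 20, 7), (20, 65, 1))),
    TrajectoryTemplate("Mainly self-employment", ((16, 20, 7), (20, 65, 3))),
)


def builtin_templates(gender: str) -> list[TrajectoryTemplate]:
    """The stock typology shapes: 8 women's templates, 2 men's.

    Every template opens with a short full-time-education segment before the
    working-life states diverge.
    """
    if gender == "female":
        return list(_FEMALE_TEMPLATES)
    if gender == "male":
        return list(_MALE_TEMPLATES)
    raise ValueError(f"gender must be 'female' or 'male', got {gender!r}")


def _default_covariate_model() -> dict:
    # Defaults echo the published cohort's baseline distribution: births
    # 1914-1945 (all three crisis cohorts populated), mean BMI ~26.5 (SD 4),
    # ~13% smokers, ~48% with >= 2 chronic conditions (Poisson mean 1.5),
    # ~30% inactive, attrition ~44/30/26 no-dropout/dropout/deceased.
    return {
        "birth_year_range": (1914, 1945),
        "baseline_year": 2006,
        "bmi_mean": 26.5,
        "bmi_sd": 4.0,
        "p_smoker": 0.13,
        "chronic_mean": 1.5,
        "p_low_activity": 0.30,
        "attrition_probs": {"no_dropout": 0.44, "dropout": 0.30, "deceased": 0.26},
    }


def _default_outcome_model(labels: tuple[str, ...]) -> dict:
    # Lifetime cancer prevalence ~11.5% at the reference -> intercept
    # logit(0.115) ~= -2.04 before covariate terms. The reference cluster
    # (first label) is pinned at log-OR 0.
    log_or = {lab: 0.0 for lab in labels}
    return {
        "intercept": -2.04,
        "log_or_cluster": log_or,
        "log_or_covariates": {
            "age_baseline": 0.0,
            "bmi": 0.0,
            "smoker": 0.0,
            "chronic_2plus": 0.0,
            "low_activity": 0.0,
        },
    }


@dataclass
class SyntheticConfig:
    """Everything needed to draw one reproducible cohort."""

    templates: list[TrajectoryTemplate]
    n_per_cluster: dict[str, int]
    noise_rate: float = 0.05
    gender: str = "female"
    covariate_model: dict = field(default_factory=_default_covariate_model)
    outcome_model: dict | None = None
    seed: int = 0
    alphabet: StateAlphabet = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        labels = [t.label for t in self.templates]
        if len(set(labels)) != len(labels):
            raise ValueError("template labels must be unique")
        unknown = set(self.n_per_cluster) - set(labels)
        if unknown:
            raise ValueError(f"n_per_cluster for unknown templates: {sorted(unknown)}")
        if self.outcome_model is None:
            self.outcome_model = _default_outcome_model(tuple(labels))
        zero = [l for l, b in self.outcome_model["log_or_cluster"].items() if b == 0.0]
        if not zero:
            raise ValueError("outcome model needs a reference cluster with log-OR 0")

    @classmethod
    def default(
        cls,
        gender: str = "female",
        n_per_cluster: int | dict[str, int] = 100,
        noise_rate: float = 0.05,
        seed: int = 0,
    ) -> "SyntheticConfig":
        templates = builtin_templates(gender)
        if isinstance(n_per_cluster, int):
            n_per_cluster = {t.label: n_per_cluster for t in templates}
        return cls(
            templates=templates,
            n_per_cluster=dict(n_per_cluster),
            noise_rate=noise_rate,
            gender=gender,
            seed=seed,
        )


def generate_panel(config: SyntheticConfig) -> tuple[SequencePanel, pd.Series]:
    """Draw the sequence panel; returns (panel, true cluster labels by subject)."""
    rng = _rng(config.seed, _STREAM_PANEL)
    n_states = len(config.alphabet)
    y0, y1 = config.covariate_model["birth_year_range"]

    sequences, labels, ids = [], [], []
    counter = 0
    for tpl in config.templates:
        n_c = config.n_per_cluster.get(tpl.label, 0)
        base = tpl.expand()
        length = base.size
        states = np.tile(base, (n_c, 1))
        if config.noise_rate > 0 and n_c > 0:
            corrupt = rng.random((n_c, length)) < config.noise_rate
            # uniform draw over the n_states - 1 states different from the original
            repl = rng.integers(1, n_states, size=(n_c, length))
            repl = repl + (repl >= states)
            states = np.where(corrupt, repl, states)
        birth_years = rng.integers(y0, y1 + 1, size=n_c)
        for i in range(n_c):
            sid = f"s{counter:05d}"
            counter += 1
            sequences.append(
                StateSequence(
                    subject_id=sid,
                    gender=config.gender,
                    birth_year=int(birth_years[i]),
                    states=states[i],
                    start_age=tpl.span[0],
                )
            )
            ids.append(sid)
            labels.append(tpl.label)
    panel = SequencePanel(config.alphabet, sequences)
    return panel, pd.Series(labels, index=ids, name="true_cluster")


def generate_covariates(
    true_labels: pd.Series,
    config: SyntheticConfig,
    birth_years: pd.Series | None = None,
) -> pd.DataFrame:
    """Draw the coded baseline covariate table, one row per subject.

    ``birth_years`` (indexed like ``true_labels``) reuses the panel's birth
    years so sequence and covariate layers agree; omitted, fresh years are
    drawn from the configured range.
    """
    from .association import code_birth_cohort  # local import avoids a cycle

    rng = _rng(config.seed, _STREAM_COVARIATES)
    cm = config.covariate_model
    n = len(true_labels)
    y0, y1 = cm["birth_year_range"]
    if birth_years is None:
        by = rng.integers(y0, y1 + 1, size=n)
    else:
        by = birth_years.reindex(true_labels.index).to_numpy(dtype=int)
    age_baseline = cm["baseline_year"] - by
    bmi = rng.normal(cm["bmi_mean"], cm["bmi_sd"], size=n).clip(15, 55)
    smoker = (rng.random(n) < cm["p_smoker"]).astype(int)
    chronic = rng.poisson(cm["chronic_mean"], size=n)
    low_activity = (rng.random(n) < cm["p_low_activity"]).astype(int)
    levels = list(cm["attrition_probs"].keys())
    probs = np.array([cm["attrition_probs"][l] for l in levels], dtype=float)
    attrition = rng.choice(levels, size=n, p=probs / probs.sum())
    return pd.DataFrame(
        {
            "subject_id": true_labels.index,
            "age_baseline": age_baseline.astype(float),
            "birth_cohort": [code_birth_cohort(int(v)) for v in by],
            "bmi": bmi,
            "smoker": smoker,
            "chronic_2plus": (chronic >= 2).astype(int),
            "low_activity": low_activity,
            "attrition": attrition,
        }
    ).reset_index(drop=True)


def generate_outcomes(
    true_labels: pd.Series,
    covariates: pd.DataFrame,
    config: SyntheticConfig,
) -> pd.Series:
    """Independent Bernoulli outcomes from the configured logistic model."""
    rng = _rng(config.seed, _STREAM_OUTCOMES)
    om = config.outcome_model
    assert om is not None
    eta = np.full(len(true_labels), float(om["intercept"]))
    eta += np.array([om["log_or_cluster"].get(lab, 0.0) for lab in true_labels])
    for cov, beta in om.get("log_or_covariates", {}).items():
        if beta and cov in covariates.columns:
            eta += beta * covariates[cov].to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    draws = (rng.random(len(eta)) < p).astype(int)
    return pd.Series(draws, index=true_labels.index, name="cancer")
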