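"""Synthetic ICU-like cohort generator.

Generates rectangular participant tables with planted demographic
structure — categorical blocks with fixed label probabilities,
continuous blocks (optionally skewed), per-variable missingness — and
selection mechanisms (uniform retention or logistic dependence on
named variables) that induce known compositional shifts. Every other
module is testable against these planted truths without any external
dataset.

Only marginal shapes and planted selection effects are emulated; no
attempt is made to match any real database's joint distributions.

Random-number discipline: one root seed is split into independent
per-variable child streams, so adding a variable to a config does not
perturb the draws of existing columns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CategoricalBlock:
    """One categorical column: labels and their probabilities (sum to 1)."""

    name: str
    labels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(p) != len(self.labels):
            raise ValueError(f"{self.name}: labels/probs length mismatch")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: probabilities sum to {p.sum()}, not 1")


@dataclass(frozen=True)
class ContinuousBlock:
    """One continuous column: location/scale, optionally right-skewed.

    With ``skewed=True`` values are drawn from a log-normal shifted and
    scaled to the requested mean and SD, giving a positive-skew shape
    typical of lab values and lengths of stay.
    """

    name: str
    mean: float
    sd: float
    skewed: bool = False


@dataclass(frozen=True)
class SelectionStep:
    """One selection mechanism applied to the current cohort.

    Either a uniform retention ``rate`` in (0, 1], or a logistic model:
    retention probability expit(intercept + Σ coef · x) where each key
    of ``coefficients`` is "column" (continuous, standardized on the
    current cohort) or "column=label" (categorical indicator).
    """

    reason: str
    rate: float | None = None
    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        if self.rate is None and not self.coefficients and self.intercept == 0.0:
            raise ValueError(
                f"selection step {self.reason!r} needs a rate or a logistic model"
            )
        if self.rate is not None and not (0.0 < self.rate <= 1.0):
            raise ValueError(f"retention rate must be in (0, 1], got {self.rate}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic cohort and its selection steps."""

    n: int
    seed: int
    categorical: tuple[CategoricalBlock, ...] = ()
    continuous: tuple[ContinuousBlock, ...] = ()
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    selection: tuple[SelectionStep, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {name!r} outside [0, 1]")


def _child_rng(seed: int, tag: str) -> np.random.Generator:
    """Independent stream keyed by (root seed, variable name)."""
    digest = hashlib.sha256(tag.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    child = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return np.random.default_rng(child)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one cohort table; reproducible for a fixed seed."""
    cols: dict[str, np.ndarray | pd.Series] = {}
    for block in config.categorical:
        rng = _child_rng(config.seed, f"cat:{block.name}")
        cols[block.name] = rng.choice(
            list(block.labels), size=config.n, p=list(block.probs)
        )
    for block in config.continuous:
        rng = _child_rng(config.seed, f"cont:{block.name}")
        if block.skewed:
            # log-normal with sigma=1, rescaled to the requested moments
            raw = rng.lognormal(mean=0.0, sigma=1.0, size=config.n)
            raw = (raw - raw.mean()) / raw.std()
            cols[block.name] = block.mean + block.sd * raw
        else:
            cols[block.name] = rng.normal(block.mean, block.sd, size=config.n)
    df = pd.DataFrame(cols)
    for name, rate in config.missing_rates.items():
        if name not in df.columns:
            raise ValueError(f"missing rate given for unknown column {name!r}")
        if rate > 0:
            rng = _child_rng(config.seed, f"miss:{name}")
            mask = rng.random(config.n) < rate
            col = df[name]
            if col.dtype.kind in "fiu":
                df[name] = col.where(~mask, np.nan)
            else:
                df[name] = col.astype(object).where(~mask, np.nan)
    return df


def _retention_probability(
    df: pd.DataFrame, step: SelectionStep
) -> np.ndarray:
    if step.rate is not None:
        return np.full(len(df), step.rate)
    logit = np.full(len(df), step.intercept, dtype=float)
    for key, coef in step.coefficients.items():
        if "=" in key:
            col, label = key.split("=", 1)
            x = (df[col].astype(str) == label).to_numpy(dtype=float)
        else:
            v = df[key].to_numpy(dtype=float)
            sd = np.nanstd(v)
            x = (v - np.nanmean(v)) / (sd if sd > 0 else 1.0)
            x = np.nan_to_num(x)
        logit += coef * x
    return 1.0 / (1.0 + np.exp(-logit))


def generate_selected_flow(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Initial table plus one boolean keep-mask per selection step.

    Each mask is drawn over the cohort remaining after the previous
    steps, realizing the configured retention model, so planted
    compositional shifts are recoverable from the drift table.
    """
    if not config.selection:
        raise ValueError("config declares no selection steps")
    df = generate_cohort(config)
    masks: list[np.ndarray] = []
    current = df
    for i, step in enumerate(config.selection):
        rng = _child_rng(config.seed, f"select:{i}:{step.reason}")
        p = _retention_probability(current, step)
        keep = rng.random(len(current)) < p
        masks.append(keep)
        current = current.loc[keep].reset_index(drop=True)
    return df, masks


def eicu_like(n: int = 10_000, seed: int = 0) -> GeneratorConfig:
    """Preset emulating the shape of a large multi-center ICU cohort.

    Six-level ethnicity, two-level sex, age and an illness-severity
    score, plus a biomarker-availability selection step whose logistic
    retention depends on severity and ethnicity — the classic
    testing-availability selection mechanism.
    """
    return GeneratorConfig(
        n=n,
        seed=seed,
        categorical=(
            CategoricalBlock(
                "ethnicity",
                ("Caucasian", "African American", "Other or Unknown",
                 "Hispanic", "Asian", "Native American"),
                (0.776, 0.116, 0.047, 0.037, 0.017, 0.007),
            ),
            CategoricalBlock("sex", ("Male", "Female"), (0.547, 0.453)),
        ),
        continuous=(
            ContinuousBlock("age", mean=62.8, sd=16.2),
            ContinuousBlock("apache_iv", mean=57.3, sd=25.8, skewed=True),
        ),
        missing_rates={"apache_iv": 0.05},
        selection=(
            SelectionStep(
                reason="No known heart disease",
                rate=0.93,
                label="Heart disease excluded",
            ),
            SelectionStep(
                reason="Troponin measured",
                intercept=-2.0,
                coefficients={"apache_iv": 0.8, "ethnicity=Caucasian": 0.4},
                label="Troponin available",
            ),
        ),
    )
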