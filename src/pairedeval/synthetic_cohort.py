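"""Synthetic paired-quiz cohorts from a binormal latent-quality model.

Every embryo carries a latent quality q: positive-outcome embryos draw
q ~ Normal(d, 1) and negative-outcome embryos q ~ Normal(0, 1), where d
is the effect size in standard-deviation units.  The scoring model
observes q + sigma_m * eps and rater r perceives q + sigma_r * eps, with
independent standard-normal noise per observer per embryo; each selector
picks the embryo whose (noisy) value is larger.  Sharing the latent q
across observers induces the correlated choices (positive inter-rater
kappa, committee gains over the mean individual) that the analysis
stack expects, while independent noise keeps each rater's accuracy a
stable trait with the closed form

    P(correct) = Phi( d / sqrt(2 (1 + sigma^2)) ),

which doubles as an oracle for parameter-recovery tests and lets noise
levels be calibrated to any target accuracy below the ceiling
Phi(d / sqrt(2)).

All randomness derives from a single integer seed through named
``numpy`` ``SeedSequence`` spawns (latents, model noise, rater noise,
display order, experience), so one seed reproduces every file byte for
byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .types import (
    ChoiceMatrix,
    EmbryoRecord,
    PairRecord,
    RaterRecord,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "expected_rater_accuracy",
    "calibrate_sigma",
    "paper_shaped_config",
    "paper_shaped_cohort",
    "write_cohort",
]

SCORE_SCALE = (0.0, 10.0)  # cosmetic affine range of exported model scores


@dataclass
class SimulationConfig:
    """Dimensions and noise levels of one synthetic cohort.

    Parameters
    ----------
    n_pairs_per_clinic
        Pairs to generate for each clinic stratum.
    n_raters
        Number of simulated raters; must match ``len(sigma_r)``.
    d
        Latent effect size: mean quality gap between positive and
        negative embryos, in SD units (d = 0 means outcomes carry no
        signal and every selector's expected accuracy is 1/2).
    sigma_r
        Per-rater perceptual noise SDs (one per rater).
    sigma_m
        Model-score noise SD.
    years_experience
        Per-rater experience in years; independent of ``sigma_r``
        unless the caller correlates them deliberately.
    seed
        Single integer reproducing the whole cohort.
    """

    n_pairs_per_clinic: Mapping[str, int]
    n_raters: int
    d: float
    sigma_r: list[float]
    sigma_m: float
    years_experience: list[float]
    seed: int

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValidationError("effect size d must be >= 0")
        if self.sigma_m < 0:
            raise ValidationError("sigma_m must be >= 0")
        if any(s < 0 for s in self.sigma_r):
            raise ValidationError("all sigma_r must be >= 0")
        if len(self.sigma_r) != self.n_raters:
            raise ValidationError("sigma_r must have one entry per rater")
        if len(self.years_experience) != self.n_raters:
            raise ValidationError("years_experience must have one entry per rater")
        if any(y < 0 for y in self.years_experience):
            raise ValidationError("years_experience must be >= 0")
        if not self.n_pairs_per_clinic:
            raise ValidationError("need at least one clinic")
        if any(n < 1 for n in self.n_pairs_per_clinic.values()):
            raise ValidationError("pair counts must be >= 1")


@dataclass
class SyntheticCohort:
    """A complete simulated study: tables plus the generating truth."""

    config: SimulationConfig
    embryos: list[EmbryoRecord]
    pairs: list[PairRecord]
    choices: ChoiceMatrix
    raters: list[RaterRecord]
    latent_positive: np.ndarray  # q of the positive embryo, per pair
    latent_negative: np.ndarray

    @property
    def model_scores(self) -> dict[str, float]:
        return {
            e.embryo_id: e.model_score
            for e in self.embryos
            if e.model_score is not None
        }

    @property
    def latent_scores(self) -> dict[str, float]:
        """Noise-free latent quality per embryo (the generating truth)."""
        out = {}
        for i, p in enumerate(self.pairs):
            out[p.positive_embryo_id] = float(self.latent_positive[i])
            out[p.negative_embryo_id] = float(self.latent_negative[i])
        return out


def expected_rater_accuracy(d: float, sigma: float) -> float:
    """Closed-form forced-choice accuracy of a noisy latent observer.

    The observer's perceived difference (q_pos + s e1) - (q_neg + s e2)
    is Normal(d, 2 (1 + sigma^2)), so P(correct) = Phi(d / sqrt(2 (1 +
    sigma^2))).  At sigma = 0 this is Phi(d / sqrt(2)), the binormal
    AUC of the latent score itself.
    """
    if d < 0 or sigma < 0:
        raise ValidationError("d and sigma must be >= 0")
    return float(norm.cdf(d / np.sqrt(2.0 * (1.0 + sigma**2))))


def calibrate_sigma(target_accuracy: float, d: float) -> float:
    """Invert :func:`expected_rater_accuracy` for the noise level.

    Solves Phi(d / sqrt(2 (1 + sigma^2))) = target for sigma; the
    target must lie strictly between 1/2 and the noiseless ceiling
    Phi(d / sqrt(2)).
    """
    if not (0.5 < target_accuracy < 1.0):
        raise ValidationError("target accuracy must lie strictly in (0.5, 1)")
    ceiling = float(norm.cdf(d / np.sqrt(2.0)))
    if target_accuracy >= ceiling:
        raise ValidationError(
            f"target accuracy {target_accuracy} is unattainable: the "
            f"noiseless ceiling at d={d} is Phi(d/sqrt(2)) = {ceiling:.6f}"
        )
    z = norm.ppf(target_accuracy)
    return float(np.sqrt(d**2 / (2.0 * z**2) - 1.0))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate embryos, pairs, model scores and rater responses."""
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_model, rng_rater, rng_display, rng_exp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    clinics = list(config.n_pairs_per_clinic)
    n_pairs = int(sum(config.n_pairs_per_clinic.values()))
    clinic_of_pair = np.repeat(
        np.arange(len(clinics)), [config.n_pairs_per_clinic[c] for c in clinics]
    )

    q_pos = config.d + rng_latent.standard_normal(n_pairs)
    q_neg = rng_latent.standard_normal(n_pairs)

    s_pos = q_pos + config.sigma_m * rng_model.standard_normal(n_pairs)
    s_neg = q_neg + config.sigma_m * rng_model.standard_normal(n_pairs)
    # cosmetic rank-preserving affine map onto the exported score scale
    lo, hi = SCORE_SCALE
    smin = min(s_pos.min(), s_neg.min())
    smax = max(s_pos.max(), s_neg.max())
    span = smax - smin if smax > smin else 1.0
    s_pos_file = lo + (hi - lo) * (s_pos - smin) / span
    s_neg_file = lo + (hi - lo) * (s_neg - smin) / span

    sigma_r = np.asarray(config.sigma_r)[:, None]
    perceived_pos = q_pos[None, :] + sigma_r * rng_rater.standard_normal(
        (config.n_raters, n_pairs)
    )
    perceived_neg = q_neg[None, :] + sigma_r * rng_rater.standard_normal(
        (config.n_raters, n_pairs)
    )
    choices = (perceived_pos > perceived_neg).astype(np.int8)

    display_coin = rng_display.integers(0, 2, size=n_pairs)

    embryos: list[EmbryoRecord] = []
    pairs: list[PairRecord] = []
    for i in range(n_pairs):
        clinic = clinics[clinic_of_pair[i]]
        eid_pos = f"E{2 * i + 1:05d}"
        eid_neg = f"E{2 * i + 2:05d}"
        embryos.append(
            EmbryoRecord(eid_pos, clinic, "positive", float(s_pos_file[i]))
        )
        embryos.append(
            EmbryoRecord(eid_neg, clinic, "negative", float(s_neg_file[i]))
        )
        pairs.append(
            PairRecord(
                pair_id=f"P{i + 1:04d}",
                clinic_id=clinic,
                positive_embryo_id=eid_pos,
                negative_embryo_id=eid_neg,
                first_displayed_embryo_id=eid_pos if display_coin[i] else eid_neg,
            )
        )

    raters = [
        RaterRecord(f"R{r + 1:02d}", float(config.years_experience[r]))
        for r in range(config.n_raters)
    ]
    matrix = ChoiceMatrix(
        [r.rater_id for r in raters], pairs, choices, raters=raters
    )
    return SyntheticCohort(
        config=config,
        embryos=embryos,
        pairs=pairs,
        choices=matrix,
        raters=raters,
        latent_positive=q_pos,
        latent_negative=q_neg,
    )


# study-shaped preset: two outcome groups totalling 1237 + 444 pairs across
# six clinics; rater accuracies spread over ~0.60-0.69, model near 0.70
PRESET_CLINIC_PAIRS = {
    "ClinicC": 500,
    "ClinicD": 400,
    "ClinicF": 337,
    "ClinicA": 150,
    "ClinicB": 150,
    "ClinicE": 144,
}
PRESET_D = 1.0
PRESET_MODEL_ACCURACY = 0.70
PRESET_RATER_ACCURACY_RANGE = (0.60, 0.69)
PRESET_EXPERIENCE_RANGE = (2.0, 37.0)
PRESET_N_RATERS = 20


def paper_shaped_config(seed: int) -> SimulationConfig:
    """Preset reproducing the reference study's dimensions.

    1681 pairs (1237 from the biochemical-pregnancy clinics C/D/F plus
    444 from the live-birth clinics A/B/E), 3362 embryos, 20 raters
    whose noise levels are calibrated to accuracies spread over
    0.60-0.69, model noise calibrated to accuracy ~0.70, and experience
    spread over 2-37 years assigned independently of rater skill.
    """
    targets = np.linspace(*PRESET_RATER_ACCURACY_RANGE, PRESET_N_RATERS)
    sigma_r = [calibrate_sigma(t, PRESET_D) for t in targets]
    sigma_m = calibrate_sigma(PRESET_MODEL_ACCURACY, PRESET_D)
    years = np.linspace(*PRESET_EXPERIENCE_RANGE, PRESET_N_RATERS)
    # shuffle experience so skill and seniority are independent
    exp_rng = np.random.default_rng(
        np.random.SeedSequence([seed, 0xE9]).generate_state(1)[0]
    )
    years = years[exp_rng.permutation(PRESET_N_RATERS)]
    return SimulationConfig(
        n_pairs_per_clinic=dict(PRESET_CLINIC_PAIRS),
        n_raters=PRESET_N_RATERS,
        d=PRESET_D,
        sigma_r=sigma_r,
        sigma_m=sigma_m,
        years_experience=[float(y) for y in years],
        seed=seed,
    )


def paper_shaped_cohort(seed: int) -> SyntheticCohort:
    """Convenience: simulate the study-shaped preset directly."""
    return simulate_cohort(paper_shaped_config(seed))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort's four tables in the standard delimited formats."""
    from . import tabular_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "embryos": out / "embryos.csv",
        "pairs": out / "pairs.csv",
        "responses": out / "responses.csv",
        "raters": out / "raters.csv",
    }
    tabular_io.write_embryo_table(cohort.embryos, paths["embryos"])
    tabular_io.write_pair_table(cohort.pairs, paths["pairs"])
    tabular_io.write_response_table(cohort.choices, paths["responses"])
    tabular_io.write_rater_table(cohort.raters, paths["raters"])
    return paths
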