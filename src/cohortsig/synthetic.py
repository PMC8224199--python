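"""Synthetic multi-cohort longitudinal microbiome data.

Emulates the structure of multi-study gastric-bypass microbiome data: several
cohorts with strong study-level compositional batch effects, a sparse
intervention signature partially shared between studies, subject random
intercepts, unbalanced longitudinal sampling (not every subject is observed at
every post-baseline timepoint), and multinomial read counts at lognormal
sequencing depths.

The generative model works on the log10 scale so that planted effects are
commensurate with the pipeline's log10 depth normalization.  For study *s*,
feature *f*, subject *i*, sample *j* at timepoint *t*:

    log-abundance  L = mu_f + a_{s,f} + delta_{s,f,t} + u_i + e_{j,f}

with mu_f ~ N(0, 1.5^2) drawn once globally, a ~ N(0, sigma_study^2),
u ~ N(0, sigma_subject^2), e ~ N(0, sigma_noise^2) and delta = 0 at baseline.
The sample composition is softmax(L) in base 10 and counts are
Multinomial(D_j, composition) with D_j ~ round(Lognormal).

Each study's planted effect decomposes as

    delta_{s,f,t} = rho_between * delta_{f,t} + sqrt(1 - rho_between^2) * eta_{s,f,t}

so rho_between tunes how much of the intervention signature is shared between
cohorts: 1 gives an identical signature everywhere, 0 gives independent
study-specific signatures of the same magnitude.  Both components are
*persistent*: delta_{f,t} = delta_f and eta_{s,f,t} = eta_{s,f} for every
post-baseline timepoint t, emulating shifts that appear early after the
intervention and remain.  Persistence is what makes contrasts at different
post-timepoints comparable at all — it drives within-study concordance, and
(scaled by rho_between) between-study concordance across unequal follow-up
schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import FeatureTable, SampleMetadata

# Default design emulating four published 16S cohorts: subject counts and
# post-surgical timepoint sets (months) with incomplete follow-up.
_DEFAULT_SUBJECTS = [30, 25, 19, 9]
_DEFAULT_TIMEPOINTS = [[0, 1, 6], [0, 3, 12, 24], [0, 6], [0, 6, 12]]

_BASELINE_LOGMEAN_SD = 1.5  # rank-abundance skew of the baseline composition


@dataclass
class SyntheticConfig:
    """All generative parameters for a multi-study simulation."""

    n_studies: int = 4
    n_subjects_per_study: list[int] = field(default_factory=lambda: list(_DEFAULT_SUBJECTS))
    n_features: int = 200
    timepoints_per_study: list[list[float]] = field(
        default_factory=lambda: [list(t) for t in _DEFAULT_TIMEPOINTS]
    )
    retention_prob: float = 0.6
    pi_signal: float = 0.2
    tau_effect: float = 1.0
    rho_between: float = 0.8
    sigma_study: float = 1.0
    sigma_subject: float = 0.5
    sigma_noise: float = 0.5
    depth_log_mean: float = 9.9   # ln scale; exp(9.9) ~ 20k reads
    depth_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")
        if self.n_features < 2:
            raise ValidationError("n_features must be >= 2")
        if len(self.n_subjects_per_study) != self.n_studies:
            raise ValidationError("n_subjects_per_study must have n_studies entries")
        if any(n < 1 for n in self.n_subjects_per_study):
            raise ValidationError("n_subjects_per_study entries must be >= 1")
        if len(self.timepoints_per_study) != self.n_studies:
            raise ValidationError("timepoints_per_study must have n_studies entries")
        for tps in self.timepoints_per_study:
            if 0 not in tps:
                raise ValidationError("timepoints_per_study: every study needs baseline 0")
            if len([t for t in tps if t > 0]) < 1:
                raise ValidationError("timepoints_per_study: every study needs >= 1 post-timepoint")
            if any(t < 0 for t in tps):
                raise ValidationError("timepoints_per_study: negative timepoint")
            if len(set(tps)) != len(tps):
                raise ValidationError("timepoints_per_study: duplicate timepoint")
        for name in ("retention_prob", "pi_signal", "rho_between"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("tau_effect", "sigma_study", "sigma_subject", "sigma_noise",
                     "depth_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def post_timepoints_union(self) -> list[float]:
        out: set[float] = set()
        for tps in self.timepoints_per_study:
            out.update(t for t in tps if t > 0)
        return sorted(out)


@dataclass
class SignatureEffects:
    """Planted log10-scale intervention effects.

    ``delta[s, f, k]`` is study *s*'s effect for feature *f* at the *k*-th
    post-baseline timepoint of ``timepoints`` (the union over studies; studies
    use only their own timepoints).  ``shared_component`` is the cross-study
    component delta_{f,t}; ``baseline_log_mean`` is the global mu_f.
    """

    delta: np.ndarray              # (n_studies, n_features, n_post_timepoints)
    shared_component: np.ndarray   # (n_features, n_post_timepoints)
    timepoints: list[float]
    signal_features: np.ndarray    # indices of features carrying a signature
    baseline_log_mean: np.ndarray  # (n_features,)


def plant_signature(config: SyntheticConfig, rng: np.random.Generator) -> SignatureEffects:
    """Draw the planted signature and the global baseline composition."""
    config.validate()
    tps = config.post_timepoints_union()
    n_f, n_t, n_s = config.n_features, len(tps), config.n_studies

    baseline = rng.normal(0.0, _BASELINE_LOGMEAN_SD, size=n_f)

    n_signal = int(np.ceil(config.pi_signal * n_f))
    signal = rng.choice(n_f, size=n_signal, replace=False) if n_signal else np.array([], dtype=int)

    shared = np.zeros((n_f, n_t))
    delta = np.zeros((n_s, n_f, n_t))
    if n_signal:
        # persistent effects: one draw per feature (and per study for the
        # independent component), broadcast over post-timepoints
        shared[signal, :] = rng.normal(0.0, config.tau_effect, size=(n_signal, 1))
        eta = np.zeros((n_s, n_f, n_t))
        eta[:, signal, :] = rng.normal(0.0, config.tau_effect, size=(n_s, n_signal, 1))
        rho = config.rho_between
        delta = rho * shared[None, :, :] + np.sqrt(1.0 - rho ** 2) * eta
        mask = np.zeros(n_f, dtype=bool)
        mask[signal] = True
        delta[:, ~mask, :] = 0.0
    return SignatureEffects(delta, shared, tps, np.sort(signal), baseline)


def simulate_cohort(
    config: SyntheticConfig,
    effects: SignatureEffects,
    study_index: int,
    rng: np.random.Generator,
) -> tuple[FeatureTable, SampleMetadata]:
    """Simulate one study's count table and sample metadata."""
    if not 0 <= study_index < config.n_studies:
        raise ValidationError(f"study_index {study_index} out of range")
    n_f = config.n_features
    study_id = f"S{study_index}"
    timepoints = sorted(config.timepoints_per_study[study_index])
    tp_col = {t: effects.timepoints.index(t) for t in timepoints if t > 0}

    # per-study per-feature baseline offsets (the compositional batch effect)
    a_sf = rng.normal(0.0, config.sigma_study, size=n_f)
    mu_sf = effects.baseline_log_mean + a_sf

    n_sub = config.n_subjects_per_study[study_index]
    u = rng.normal(0.0, config.sigma_subject, size=n_sub)

    sample_ids: list[str] = []
    meta_rows: list[tuple] = []
    cols: list[np.ndarray] = []
    for i in range(n_sub):
        subject_id = f"{study_id}_P{i:03d}"
        for t in timepoints:
            if t > 0 and rng.random() >= config.retention_prob:
                continue
            log_abund = mu_sf + u[i] + rng.normal(0.0, config.sigma_noise, size=n_f)
            if t > 0:
                log_abund = log_abund + effects.delta[study_index, :, tp_col[t]]
            # softmax in base 10, guarded against overflow
            log_abund = log_abund - log_abund.max()
            comp = np.power(10.0, log_abund)
            comp /= comp.sum()
            depth = max(1, int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sd))))
            counts = rng.multinomial(depth, comp)
            sid = f"{study_id}_P{i:03d}_m{t:g}"
            sample_ids.append(sid)
            meta_rows.append((sid, subject_id, study_id, float(t)))
            cols.append(counts)

    feature_ids = [f"F{k:04d}" for k in range(n_f)]
    values = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=feature_ids, columns=sample_ids
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows, columns=list(
        ("sample_id", "subject_id", "study_id", "timepoint_months"))))
    return FeatureTable(values, is_count=True), meta


def simulate_multistudy(
    config: SyntheticConfig, return_effects: bool = False
):
    """Simulate every study from one master seed.

    The master seed deterministically spawns independent substreams: one for
    the planted signature and one per study, so identical configs give
    bit-identical output and per-study draws do not interact.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_studies + 1)
    effects = plant_signature(config, np.random.default_rng(children[0]))
    datasets = [
        simulate_cohort(config, effects, s, np.random.default_rng(children[s + 1]))
        for s in range(config.n_studies)
    ]
    if return_effects:
        return datasets, effects
    return datasets
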