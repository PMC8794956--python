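"""End-to-end orchestration: cohort -> preprocessing -> features ->
ensembles -> inertia statistics.

The stages mirror the analysis workflow: band-pass the EEG, derive the
high-EMG movement mask, estimate per-channel sigma and mask artifactual 4-s
windows, mean re-reference, compute multitaper window spectra for M2/V1,
build the 482-dim centered feature matrix over the three recording sources,
reduce to 50 PCs, train real and shuffled-label ensembles, and evaluate
balanced accuracy on the steady-state test period.  Every stage seed is
spawned deterministically from the run seed, so a configuration fully
determines the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import emg_tone
from . import inertia_analysis as ia
from . import preprocess as pp
from . import spectral_features as sf
from .synthetic_data import (
    Cohort,
    CohortConfig,
    IndividualRecordings,
    SyntheticRecording,
    generate_cohort,
)

__all__ = [
    "AnalysisParams",
    "PipelineConfig",
    "PreprocessedRecording",
    "preprocess_recording",
    "features_for_individual",
    "IndividualResult",
    "analyze_individual",
    "run_pipeline",
    "train_population_ensemble",
]

_FINAL_ONSET = {"induction": 1800.0, "emergence": 7200.0}
_FIRST_STEP_ONSET = 1800.0


@dataclass(frozen=True)
class AnalysisParams:
    """Stage parameters of the analysis half of the pipeline."""

    n_classifiers: int = 250
    methods: tuple = ("lda",)
    include_null: bool = True
    n_per_class: int = 260
    pca_components: int = 50
    train_window_s: tuple = clf.TRAIN_WINDOW_S
    test_window_s: tuple = ia.TEST_WINDOW_S
    early_period_min: tuple = ia.EARLY_PERIOD_MIN
    late_period_min: tuple = ia.LATE_PERIOD_MIN
    full_period_min: tuple = (30.0, 130.0)
    rereference: bool = True
    artifact: pp.ArtifactDetectionParams = field(
        default_factory=pp.ArtifactDetectionParams
    )
    bootstrap_samples: int = 10_000
    alpha: float = 0.05
    population: bool = False
    svm_kernel: str = "rbf"

    @property
    def periods_min(self) -> tuple:
        out = [tuple(self.early_period_min), tuple(self.late_period_min),
               tuple(self.full_period_min)]
        seen = []
        for p in out:
            if p not in seen:
                seen.append(p)
        return tuple(seen)


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["spans"] = (
            self.cohort.spans if isinstance(self.cohort.spans, str)
            else {k: [list(s) for s in v] for k, v in self.cohort.spans.items()}
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohort = dict(d.get("cohort", {}))
        if isinstance(cohort.get("spans"), dict):
            cohort["spans"] = {
                k: tuple(tuple(s) for s in v) for k, v in cohort["spans"].items()
            }
        analysis = dict(d.get("analysis", {}))
        if "artifact" in analysis and isinstance(analysis["artifact"], dict):
            analysis["artifact"] = pp.ArtifactDetectionParams(**analysis["artifact"])
        for key in ("methods", "train_window_s", "test_window_s",
                    "early_period_min", "late_period_min", "full_period_min"):
            if key in analysis and isinstance(analysis[key], list):
                analysis[key] = tuple(analysis[key])
        return cls(
            cohort=CohortConfig(**cohort),
            analysis=AnalysisParams(**analysis),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedRecording:
    """Clean re-referenced EEG segments plus the masks that produced them."""

    recording: SyntheticRecording
    segments: list               # (t_start_s, eeg (n_ch, n) float)
    window_masks: list           # bool per 4-s window per segment (M2|V1)
    channel_sigma_uv: dict
    emg_threshold_log_uv: float
    emg_high_fraction: float


def preprocess_recording(
    rec: SyntheticRecording,
    params: pp.ArtifactDetectionParams = pp.ArtifactDetectionParams(),
    rereference: bool = True,
) -> PreprocessedRecording:
    """Run the signal-conditioning chain on one recording.

    Per-channel sigma for the 6-sigma rule is a single scalar over the whole
    recording (all synthesized segments), excluding hard-limit samples and
    high-EMG seconds.  A window is excluded when either analysis channel
    (M2, V1) trips the artifact rule in it.
    """
    fs = rec.fs
    n_ch = len(rec.channel_names)
    filt_segs = []
    emg_rms_parts = []
    for seg in rec.segments:
        eeg = np.stack([pp.bandpass_eeg(seg.eeg[ch], fs=fs) for ch in range(n_ch)])
        filt_segs.append(eeg)
        emg_rms_parts.append(
            emg_tone.emg_rms_series(emg_tone.highpass_emg(seg.emg.astype(float), fs=fs),
                                    fs=fs, t0_s=seg.t_start_s)
        )
    rms = emg_tone.RmsSeries(
        values=np.concatenate([r.values for r in emg_rms_parts]),
        times=np.concatenate([r.times for r in emg_rms_parts]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tone = emg_tone.high_tone_threshold(rms)

    seg_seconds = [int(round(seg.n_samples / fs)) for seg in rec.segments]
    sec_offsets = np.cumsum([0] + seg_seconds)

    # per-channel sigma and window masks on the concatenated recording
    win_per_seg = [int(seg.n_samples // int(params.window_s * fs))
                   for seg in rec.segments]
    channel_sigma = {}
    channel_masks = []  # per channel: concatenated window mask
    concat_emg_mask = tone.mask
    for ch in range(n_ch):
        x_all = np.concatenate([eeg[ch] for eeg in filt_segs])
        am = pp.detect_artifact_windows(
            x_all, fs=fs, params=params, high_emg_mask=concat_emg_mask
        )
        channel_sigma[rec.channel_names[ch]] = am.sigma_uv
        channel_masks.append(am.mask)

    # combined analysis-channel mask, split back per segment
    m2v1 = channel_masks[0] | channel_masks[1]
    window_masks = []
    clean_segments = []
    w0 = 0
    for si, seg in enumerate(rec.segments):
        nw = win_per_seg[si]
        window_masks.append(m2v1[w0: w0 + nw])
        eeg = filt_segs[si]
        if rereference and n_ch >= 2:
            win = int(params.window_s * fs)
            valid = np.ones_like(eeg, dtype=bool)
            for ch in range(n_ch):
                seg_mask = channel_masks[ch][w0: w0 + nw]
                bad = np.repeat(seg_mask, win)
                valid[ch, : bad.size] = ~bad
            eeg = pp.mean_rereference(eeg, sample_valid=valid)
        clean_segments.append((seg.t_start_s, eeg))
        w0 += nw
    return PreprocessedRecording(
        recording=rec,
        segments=clean_segments,
        window_masks=window_masks,
        channel_sigma_uv=channel_sigma,
        emg_threshold_log_uv=tone.threshold_log_uv,
        emg_high_fraction=tone.high_fraction,
    )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _recording_psd(prep: PreprocessedRecording):
    """Multitaper PSD of the analysis channels over all unmasked windows."""
    psd_m2, psd_v1, times = [], [], []
    for (t0, eeg), mask in zip(prep.segments, prep.window_masks):
        p_m2, t_m2 = sf.window_psd(eeg[0], fs=prep.recording.fs, t0_s=t0,
                                   artifact_mask=mask)
        p_v1, _ = sf.window_psd(eeg[1], fs=prep.recording.fs, t0_s=t0,
                                artifact_mask=mask)
        psd_m2.append(p_m2)
        psd_v1.append(p_v1)
        times.append(t_m2)
    return (np.concatenate(psd_m2), np.concatenate(psd_v1),
            np.concatenate(times))


def _attach_step_times(meta: pd.DataFrame) -> pd.DataFrame:
    """Add seconds-since-0.6%-step-onset per source."""
    onset = np.where(
        meta["source"] == "emergence",
        _FINAL_ONSET["emergence"],
        np.where(meta["source"] == "induction",
                 _FINAL_ONSET["induction"], _FIRST_STEP_ONSET),
    )
    meta = meta.copy()
    meta["step_time_s"] = meta["time_s"] - onset
    return meta


def features_for_individual(
    pair: IndividualRecordings,
    params: AnalysisParams = AnalysisParams(),
):
    """Preprocess both recordings and build the individual's feature space.

    Returns ``(feature_set, windows, preps)`` where ``feature_set.meta``
    carries source and step-time columns used by training/test selection.
    The emergence recording contributes two sources: its first 0.6% step
    (the induction arm of the emergence exposure) and its final step.
    """
    preps = {}
    for arm, rec in (("induction", pair.induction), ("emergence", pair.emergence)):
        preps[arm] = preprocess_recording(rec, params=params.artifact,
                                          rereference=params.rereference)
    m2_i, v1_i, t_i = _recording_psd(preps["induction"])
    m2_e, v1_e, t_e = _recording_psd(preps["emergence"])
    final_onset = _FINAL_ONSET["emergence"]
    pre = t_e < final_onset
    sources = {
        "induction": {"M2": m2_i, "V1": v1_i, "times": t_i},
        "emergence_induction_arm": {
            "M2": m2_e[pre], "V1": v1_e[pre], "times": t_e[pre]},
        "emergence": {
            "M2": m2_e[~pre], "V1": v1_e[~pre], "times": t_e[~pre]},
    }
    windows = sf.build_feature_matrix(sources)
    windows.meta = _attach_step_times(windows.meta)
    feature_set = sf.fit_pca(windows, k=params.pca_components)
    feature_set.meta = windows.meta.copy()
    return feature_set, windows, preps


# ---------------------------------------------------------------------------
# per-individual analysis
# ---------------------------------------------------------------------------

@dataclass
class IndividualResult:
    individual_id: object
    feature_set: sf.FeatureSet
    traces: dict          # (method, null) -> AccuracyTrace
    summary: dict


def _early_late_pairs(trace: ia.AccuracyTrace, params: AnalysisParams,
                      individual) -> pd.DataFrame:
    early = trace.period_label(params.early_period_min)
    late = trace.period_label(params.late_period_min)
    t = trace.table.pivot(index="classifier", columns="period", values="accuracy")
    return pd.DataFrame({
        "individual": individual,
        "classifier": t.index.to_numpy(),
        "early": t[early].to_numpy(),
        "late": t[late].to_numpy(),
    })


def analyze_individual(
    pair: IndividualRecordings,
    params: AnalysisParams = AnalysisParams(),
    seed: int = 0,
) -> IndividualResult:
    """Full per-individual analysis: features, ensembles, accuracy traces."""
    feature_set, _, preps = features_for_individual(pair, params)
    scores, meta = feature_set.scores, feature_set.meta
    traces = {}
    summary = {
        "individual": pair.individual_id,
        "explained_variance_50pc": float(
            feature_set.explained_variance_ratio.sum()),
        "emg_high_fraction": {
            arm: preps[arm].emg_high_fraction for arm in preps},
        "n_windows": int(len(meta)),
    }
    base = np.random.SeedSequence(seed)
    method_seeds = {
        m: int(s.generate_state(1)[0] % (2 ** 31))
        for m, s in zip(params.methods, base.spawn(len(params.methods)))
    }
    for method in params.methods:
        for null in ((False, True) if params.include_null else (False,)):
            ens = clf.train_ensemble(
                scores, meta, n_members=params.n_classifiers, method=method,
                base_seed=method_seeds[method] + (500_000 if null else 0),
                null=null, n_per_class=params.n_per_class,
                train_window_s=params.train_window_s,
                svm_kernel=params.svm_kernel,
            )
            trace = ia.evaluate_ensemble(
                ens, scores, meta, periods_min=params.periods_min,
                test_window_s=params.test_window_s,
            )
            trace.individual = pair.individual_id
            traces[(method, null)] = trace
    return IndividualResult(
        individual_id=pair.individual_id, feature_set=feature_set,
        traces=traces, summary=summary,
    )


# ---------------------------------------------------------------------------
# population-level training (leave-one-out)
# ---------------------------------------------------------------------------

def train_population_ensemble(
    cohort_features: dict,
    held_out_id,
    n_members: int = 250,
    method: str = "lda",
    base_seed: int = 0,
    null: bool = False,
    n_per_individual: int = 260,
    train_window_s=clf.TRAIN_WINDOW_S,
) -> clf.ClassifierEnsemble:
    """Ensemble trained on the other individuals' windows (shared feature
    space); member i resamples its 1300-per-class set with seed
    base_seed + i."""
    members = []
    for i in range(n_members):
        ts = clf.assemble_population_training_set(
            cohort_features, held_out_id, n_per_individual=n_per_individual,
            seed=base_seed + i, train_window_s=train_window_s,
        )
        if null:
            ts = clf.shuffle_labels(ts, seed=base_seed + 100_000 + i)
        members.append(clf.train_lda(ts) if method == "lda"
                       else clf.train_svm(ts))
    return clf.ClassifierEnsemble(members=members, method=method,
                                  base_seed=base_seed, null=null,
                                  provenance={"held_out": held_out_id})


# ---------------------------------------------------------------------------
# cohort-level pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
) -> tuple:
    """Run the whole analysis; returns (InertiaReport, results, pairs_table).

    ``cohort`` may be supplied (e.g. imported recordings); otherwise it is
    generated from ``config.cohort`` with ``config.seed``.  Identical
    (config, seed) produce identical reports.
    """
    params = config.analysis
    if cohort is None:
        cohort = generate_cohort(config=config.cohort, seed=config.seed)
    if params.population and len(cohort.individuals) < 2:
        warnings.warn("population training skipped: cohort has one individual")

    ss = np.random.SeedSequence(config.seed + 1_000_003)
    ind_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(len(cohort.individuals))]
    results = [
        analyze_individual(pair, params, seed=ind_seeds[i])
        for i, pair in enumerate(cohort.individuals)
    ]

    full_label = f"{params.full_period_min[0]:g}-{params.full_period_min[1]:g}"
    per_individual = []
    pairs_frames = {m: [] for m in params.methods}
    method_medians = {m: {} for m in params.methods}
    for res in results:
        entry = dict(res.summary)
        for method in params.methods:
            real = res.traces[(method, False)]
            acc = real.accuracies(full_label)
            method_tag = sum(ord(c) for c in method)  # stable across runs
            med, lo, hi = ia.bootstrap_median_ci(
                acc, n_boot=params.bootstrap_samples,
                seed=config.seed + 17 * (method_tag % 1000 + 1))
            block = {
                "median_accuracy": med,
                "ci95": [lo, hi],
            }
            if (method, True) in res.traces:
                null_acc = res.traces[(method, True)].accuracies(full_label)
                null_cmp = ia.compare_to_null(acc, null_acc, alpha=params.alpha)
                block["null_comparison"] = {
                    "p_value": null_cmp.p_value,
                    "statistic": null_cmp.statistic,
                    "median_null": null_cmp.extra["median_null"],
                    "inertia_call": null_cmp.extra["inertia_call"],
                }
            entry[method] = block
            method_medians[method][res.individual_id] = med
            pairs_frames[method].append(
                _early_late_pairs(real, params, res.individual_id))
        per_individual.append(entry)

    method_comparison = None
    if len(params.methods) >= 2 and len(results) >= 3:
        table = pd.DataFrame(method_medians)
        cmp_res = ia.compare_methods(table)
        method_comparison = {
            "test": cmp_res.test, "statistic": cmp_res.statistic,
            "p_value": cmp_res.p_value, "n_blocks": cmp_res.extra["n_blocks"],
            "methods": cmp_res.extra["methods"],
        }

    early_late = {}
    pairs_table = {}
    for method in params.methods:
        pairs = pd.concat(pairs_frames[method], ignore_index=True)
        pairs_table[method] = pairs
        el = ia.early_late_comparison(pairs, alpha=params.alpha)
        early_late[method] = {
            "wilcoxon_p": el.wilcoxon.p_value,
            "wilcoxon_statistic": el.wilcoxon.statistic,
            "n_pairs": el.wilcoxon.n[0],
            "median_early": el.wilcoxon.extra["median_early"],
            "median_late": el.wilcoxon.extra["median_late"],
            "decrease": el.wilcoxon.extra["decrease"],
            "anova": el.anova,
            "per_individual": el.per_individual,
        }

    report = ia.InertiaReport(
        per_individual=per_individual,
        method_comparison=method_comparison,
        early_late=early_late,
        config=config.to_dict(),
    )
    return report, results, pairs_table
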