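"""Synthetic oGTT metabolomics cohorts with machine-readable ground truth.

The generator emulates the statistical structure the analysis assumes: log10
intensities built from four temporal archetypes (sustained decline, rise with
late plateau, V-shape, rise-then-fall), a per-subject random intercept,
Gaussian measurement noise, planted standardized group effects on log-scale
windowed AUCs, one enriched chemical class (optionally a biphasic class that
is elevated early and suppressed late in the almond arm), QC replicates with
controlled relative standard deviation, blank samples (including metabolites
constructed to fail the blank filter), MCAR missingness, and Matsuda-index
values realizing exact within-group correlations with a designated
metabolite's AUC.

Everything is driven by a single seeded RNG: identical ``SimConfig`` yields
byte-identical output tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .auc import TimeWindow, trapezoid_weights
from .config import ARCHETYPE_LABELS, SimConfig
from .data import (
    GROUPS,
    ROLE_BLANK,
    ROLE_QC,
    ROLE_STUDY,
    GroundTruth,
    TimeCourseDataset,
    fingerprint_to_hex,
)

#: Pool of chemical-class names assigned to simulated metabolites. The first
#: entry is the planted enriched class; "biphasic_lipids" is used when a
#: biphasic class is requested.
CLASS_NAMES = (
    "unsaturated_triglycerides",
    "saturated_triglycerides",
    "lysophosphatidylcholines",
    "phosphatidylcholines",
    "oxylipins",
    "amino_acids",
    "carbohydrates",
    "organic_acids",
    "nucleotides",
    "cholesteryl_esters",
)
BIPHASIC_CLASS = "biphasic_lipids"


def archetype_shapes(timepoints: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-variance mean-zero trajectory shapes on the sampling grid.

    decline: monotone fall; rise_plateau: monotone rise with flattening
    slope; v_shape: sharp drop at the first post-baseline point then steady
    rise; rise_fall: rise over the first half, fall thereafter.
    """
    t = np.asarray(timepoints, dtype=float)
    f = np.arange(len(t)) / (len(t) - 1)  # rank position, not clock time
    raw = {
        "decline": 1.0 - 2.0 * f,
        "rise_plateau": 2.0 * np.sqrt(f) - 1.0,
        "v_shape": np.concatenate(([0.5], np.linspace(-1.0, 1.0, len(t) - 1))),
        "rise_fall": np.sin(np.pi * f),
    }
    out = {}
    for k, v in raw.items():
        out[k] = (v - v.mean()) / v.std(ddof=1)
    return out


def _log_auc_sd(config: SimConfig, window: TimeWindow) -> float:
    """Closed-form SD of a subject's log10-scale window AUC under the model."""
    w = trapezoid_weights(np.asarray(config.timepoints, float), window)
    return float(
        np.sqrt(
            config.subject_sd**2 * w.sum() ** 2
            + config.noise_sd**2 * (w**2).sum()
        )
    )


def _special_ids(config: SimConfig, mets: list[str]) -> dict[str, list[str]]:
    """Deterministic partition of metabolite ids into special roles.

    Artifact metabolites occupy the tail of the id list; the biphasic class
    (if any) sits just before them. Derivable from the config alone so that
    :func:`generate_blank_qc` does not need the GroundTruth object.
    """
    n = config.n_metabolites
    hi = mets[n - config.n_high_rsd : n] if config.n_high_rsd else []
    bl_end = n - config.n_high_rsd
    bl = mets[bl_end - config.n_blank_artifacts : bl_end] if config.n_blank_artifacts else []
    bi_end = bl_end - config.n_blank_artifacts
    bi = mets[bi_end - config.biphasic_class_size : bi_end] if config.biphasic_class_size else []
    return {"high_rsd": hi, "blank_artifacts": bl, "biphasic": bi}


def generate_cohort(config: SimConfig) -> tuple[TimeCourseDataset, GroundTruth]:
    """Simulate one two-arm oGTT cohort plus its ground truth."""
    rng = np.random.default_rng([config.seed, 0])
    tps = np.asarray(config.timepoints, dtype=float)
    n_t = len(tps)
    n_sub = 2 * config.n_per_group
    n_met = config.n_metabolites
    mets = [f"M{i:04d}" for i in range(n_met)]
    special = _special_ids(config, mets)
    artifact_set = set(special["high_rsd"]) | set(special["blank_artifacts"])
    regular = [m for m in mets if m not in artifact_set]

    # --- archetypes -----------------------------------------------------
    shapes = archetype_shapes(tps)
    labels = list(ARCHETYPE_LABELS)
    arch_idx = rng.choice(len(labels), size=len(regular), p=list(config.archetype_weights))
    archetype_of = {m: labels[k] for m, k in zip(regular, arch_idx)}

    # --- planted group effects ------------------------------------------
    full_window = TimeWindow(tps[0], tps[-1])
    post_idx = np.arange(1, n_t)  # shift applies post-baseline only
    w_full = trapezoid_weights(tps, full_window)
    denom_full = w_full[post_idx].sum()
    delta_full = config.planted_g * _log_auc_sd(config, full_window) / denom_full

    eligible = [m for m in regular if m not in set(special["biphasic"])]
    affected_ids = list(rng.choice(eligible, size=config.n_affected, replace=False))
    signs = {}
    for j, m in enumerate(affected_ids):
        # enriched-class members share a direction; extras alternate
        signs[m] = 1.0 if j < config.enriched_class_size else (1.0 if j % 2 == 0 else -1.0)

    # biphasic: up early, down late (almond arm)
    half = 1 + (n_t - 1) // 2
    early_idx = np.arange(1, half)
    late_idx = np.arange(half, n_t)
    early_win = TimeWindow(tps[0], tps[half - 1])
    late_win = TimeWindow(tps[half - 1], tps[-1])
    w_early = trapezoid_weights(tps, early_win)
    w_late = trapezoid_weights(tps, late_win)
    delta_early = (
        config.planted_g * _log_auc_sd(config, early_win) / w_early[early_idx].sum()
        if config.biphasic_class_size
        else 0.0
    )
    # late window: every grid point in it is shifted
    delta_late = (
        config.planted_g * _log_auc_sd(config, late_win) / w_late[late_idx].sum()
        if config.biphasic_class_size
        else 0.0
    )

    # --- chemical classes ------------------------------------------------
    class_of: dict[str, str] = {}
    enriched_class = CLASS_NAMES[0] if (config.enriched_class_size and config.n_affected) else None
    enriched_members = affected_ids[: config.enriched_class_size] if enriched_class else []
    for m in enriched_members:
        class_of[m] = enriched_class
    for m in special["biphasic"]:
        class_of[m] = BIPHASIC_CLASS
    pool = [c for c in CLASS_NAMES if c != enriched_class]
    extra_needed = max(0, config.n_classes - 1 - len(pool))
    pool = pool + [f"class_{k:02d}" for k in range(extra_needed)]
    pool = pool[: max(1, config.n_classes - (1 if enriched_class else 0))]
    rest = [m for m in mets if m not in class_of]
    for j, m in enumerate(rest):
        class_of[m] = pool[j % len(pool)]

    # --- intensity tensor (subject x time x metabolite), log10 scale -----
    base = rng.normal(config.base_log_mean, config.base_log_sd, size=n_met)
    shape_mat = np.zeros((n_t, n_met))
    for j, m in enumerate(mets):
        if m in archetype_of:
            shape_mat[:, j] = config.archetype_amplitude * shapes[archetype_of[m]]
    b_subj = rng.normal(0.0, config.subject_sd, size=(n_sub, n_met))
    noise = rng.normal(0.0, config.noise_sd, size=(n_sub, n_t, n_met))

    log_x = base[None, None, :] + shape_mat[None, :, :] + b_subj[:, None, :] + noise
    almond = np.arange(config.n_per_group)  # first half of subjects
    met_pos = {m: j for j, m in enumerate(mets)}
    for m in affected_ids:
        j = met_pos[m]
        log_x[np.ix_(almond, post_idx, [j])] += signs[m] * delta_full
    for m in special["biphasic"]:
        j = met_pos[m]
        log_x[np.ix_(almond, early_idx, [j])] += delta_early
        log_x[np.ix_(almond, late_idx, [j])] -= delta_late

    # --- sample/metadata frames ------------------------------------------
    subj_ids = [f"subj{i:03d}" for i in range(n_sub)]
    group_of = {
        s: (GROUPS[0] if i < config.n_per_group else GROUPS[1])
        for i, s in enumerate(subj_ids)
    }
    sample_ids, meta_rows = [], []
    for i, s in enumerate(subj_ids):
        for k, t in enumerate(tps):
            sample_ids.append(f"{s}_t{int(t):03d}")
            meta_rows.append((s, group_of[s], ROLE_STUDY, float(t)))
    samples = pd.DataFrame(
        meta_rows,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["subject_id", "group", "role", "timepoint_min"],
    )
    values = (10.0 ** log_x).reshape(n_sub * n_t, n_met)
    intensities = pd.DataFrame(values, index=samples.index, columns=mets)

    # --- Matsuda index with exact planted correlations --------------------
    mi_metabolite = affected_ids[0] if affected_ids else mets[0]
    j = met_pos[mi_metabolite]
    log_auc = np.tensordot(log_x[:, :, j], w_full, axes=([1], [0]))  # per subject
    mi = np.empty(n_sub)
    planted_corr = []
    for g_i, (grp, r) in enumerate(
        zip(GROUPS, (config.mi_corr_almond, config.mi_corr_cracker))
    ):
        sl = slice(g_i * config.n_per_group, (g_i + 1) * config.n_per_group)
        a = log_auc[sl]
        a_std = (a - a.mean()) / a.std(ddof=1)
        e = rng.standard_normal(config.n_per_group)
        e = e - e.mean()
        e = e - a_std * (e @ a_std) / (a_std @ a_std)  # orthogonalize
        e_std = e / e.std(ddof=1)
        mi[sl] = 6.0 + 2.0 * (r * a_std + np.sqrt(1 - r**2) * e_std)
        planted_corr.append((mi_metabolite, grp, float(r)))
    clinical = pd.DataFrame({"matsuda": mi}, index=pd.Index(subj_ids, name="subject_id"))

    # --- annotations: classes, fingerprints, reactant pairs ----------------
    classes = sorted(set(class_of.values()))
    class_fp = {c: rng.random(64) < 0.35 for c in classes}
    fp_hex = {}
    for m in mets:
        fp = class_fp[class_of[m]].copy()
        flip = rng.choice(64, size=4, replace=False)
        fp[flip] = ~fp[flip]
        if not fp.any():
            fp[0] = True
        fp_hex[m] = fingerprint_to_hex(fp)
    annotations = pd.DataFrame(
        {
            "chem_class": [class_of[m] for m in mets],
            "fingerprint": [fp_hex[m] for m in mets],
            "kegg_id": [f"C{5000 + k:05d}" for k in range(n_met)],
        },
        index=pd.Index(mets, name="metabolite"),
    )
    pair_rows = []
    for c in classes:
        members = [m for m in mets if class_of[m] == c]
        for a, b in zip(members[:-1], members[1:]):  # chain within class
            pair_rows.append((a, b))
    kegg_pairs = pd.DataFrame(pair_rows, columns=["metabolite_a", "metabolite_b"])

    # --- MCAR missingness ---------------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities = intensities.mask(mask)

    dataset = TimeCourseDataset(samples, intensities, annotations, clinical, kegg_pairs)
    truth = GroundTruth(
        affected={m: signs[m] * config.planted_g for m in affected_ids},
        archetype_of=archetype_of,
        enriched_class=enriched_class,
        enriched_members=enriched_members,
        biphasic_class=BIPHASIC_CLASS if config.biphasic_class_size else None,
        biphasic_members=special["biphasic"],
        planted_correlations=planted_corr,
        blank_artifacts=special["blank_artifacts"],
        high_rsd_metabolites=special["high_rsd"],
        mi_metabolite=mi_metabolite,
    )
    return dataset, truth


def _values_with_exact_rsd(
    rng: np.random.Generator, n: int, center: float, target_rsd: float
) -> np.ndarray:
    """Positive values whose sample RSD (SD/mean, ddof=1) equals the target.

    Draws a standardized pattern and root-solves a multiplicative spread so
    the planted QC failure/pass margins are deterministic, not sampling luck.
    """
    z = rng.standard_normal(n)
    u = (z - z.mean()) / z.std(ddof=1)

    def rsd(a: float) -> float:
        v = np.exp(a * u)
        return v.std(ddof=1) / v.mean()

    a = brentq(lambda a: rsd(a) - target_rsd, 1e-9, 5.0, xtol=1e-12)
    v = np.exp(a * u)
    return center * v / np.median(v)


def generate_blank_qc(config: SimConfig, dataset: TimeCourseDataset) -> TimeCourseDataset:
    """Append QC-replicate and blank samples to a generated cohort.

    QC rows emulate replicate injections of a pooled sample: per metabolite
    the replicate RSD is drawn from ``qc_rsd_range``, except for the planted
    high-RSD metabolites which get ``qc_rsd_high``. Blank rows sit at
    ``blank_level`` of the study median except for the planted blank
    artifacts, whose blanks are resampled from the study values and scaled
    up so the median sample/blank ratio falls below 1.
    """
    if dataset is None:
        raise ValueError("generate_blank_qc requires a dataset from generate_cohort")
    rng = np.random.default_rng([config.seed, 1])
    mets = dataset.metabolites
    special = _special_ids(config, [f"M{i:04d}" for i in range(config.n_metabolites)])
    hi_rsd = set(special["high_rsd"]) & set(mets)
    blank_art = set(special["blank_artifacts"]) & set(mets)
    study = dataset.matrix(ROLE_STUDY)

    qc_vals = np.empty((config.qc_replicates, len(mets)))
    for j, m in enumerate(mets):
        med = float(np.nanmedian(study[m]))
        target = (
            config.qc_rsd_high
            if m in hi_rsd
            else rng.uniform(*config.qc_rsd_range)
        )
        qc_vals[:, j] = _values_with_exact_rsd(rng, config.qc_replicates, med, target)

    blank_vals = np.empty((config.n_blanks, len(mets)))
    for j, m in enumerate(mets):
        obs = study[m].dropna().to_numpy()
        if m in blank_art:
            blank_vals[:, j] = (
                rng.choice(obs, size=config.n_blanks, replace=True)
                * config.blank_artifact_scale
            )
        else:
            med = float(np.median(obs))
            blank_vals[:, j] = med * config.blank_level * np.exp(
                rng.normal(0.0, 0.3, size=config.n_blanks)
            )

    qc_ids = [f"qc{k:02d}" for k in range(config.qc_replicates)]
    blank_ids = [f"blank{k:02d}" for k in range(config.n_blanks)]
    extra_meta = pd.DataFrame(
        {
            "subject_id": [None] * (len(qc_ids) + len(blank_ids)),
            "group": [None] * (len(qc_ids) + len(blank_ids)),
            "role": [ROLE_QC] * len(qc_ids) + [ROLE_BLANK] * len(blank_ids),
            "timepoint_min": [np.nan] * (len(qc_ids) + len(blank_ids)),
        },
        index=pd.Index(qc_ids + blank_ids, name="sample_id"),
    )
    extra_int = pd.DataFrame(
        np.vstack([qc_vals, blank_vals]), index=extra_meta.index, columns=mets
    )
    return TimeCourseDataset(
        samples=pd.concat([dataset.samples, extra_meta]),
        intensities=pd.concat([dataset.intensities, extra_int]),
        annotations=dataset.annotations,
        clinical=dataset.clinical,
        kegg_pairs=dataset.kegg_pairs,
    )


def write_cohort(
    dataset: TimeCourseDataset, truth: GroundTruth, out_dir
) -> None:
    """Persist a generated cohort and its ground truth to a directory."""
    path = dataset.to_dir(out_dir)
    truth.to_json(path / "ground_truth.json")
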