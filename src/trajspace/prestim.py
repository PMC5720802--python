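"""Pre-stimulus template-similarity analysis of unconscious discrimination.

For unseen trials only: per-orientation "evoked templates" are built by
averaging each sensor's activity over a post-stimulus window [0, w) across
trials; each trial's mean pre-stimulus map over [-w, 0) is spatially
correlated (Pearson, across sensors) with both templates and the trial is
assigned to the group whose template correlates more strongly. Signal
detection theory then quantifies the response bias (criterion c) per
group; a criterion difference between groups in the direction of the
better-matching template indicates that pre-stimulus activity biases the
unconscious decision.

Sign conventions: "left" is the signal class, so H = P(respond left |
left stimulus), FA = P(respond left | right stimulus), d' = z(H) - z(FA)
and c = -(z(H) + z(FA)) / 2; a *negative* c means a liberal bias toward
answering "left". These conventions are recorded in the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .core import EpochedRecording, sensor_lobes
from .permstats import bh_fdr

__all__ = [
    "PrestimConfig",
    "SDTResult",
    "build_templates",
    "similarity_sort",
    "sdt_measures",
    "subject_group_criteria",
    "aggregate_prestim",
    "run_prestim_analysis",
]

REGIONS = ("all", "occipital", "temporal", "parietal", "central", "frontal")


@dataclass
class PrestimConfig:
    window_lengths: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    regions: tuple = REGIONS
    band: str = "broadband"

    def __post_init__(self):
        if any(w <= 0 for w in self.window_lengths):
            raise ValueError("window lengths must be positive")


@dataclass
class SDTResult:
    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float
    n_trials: int
    corrected: bool
    #: documented sign convention
    convention: str = "signal='left'; c<0 = liberal toward 'left'"


def build_templates(rec: EpochedRecording, w: float) -> dict:
    """Per-orientation mean sensor map over the post-stimulus window [0, w)."""
    mask = rec.time_mask(0.0, w)
    if not mask.any():
        raise ValueError(f"window [0, {w}) contains no samples")
    ori = rec.meta["orientation"].to_numpy()
    out = {}
    for label in ("left", "right"):
        idx = np.flatnonzero(ori == label)
        if idx.size < 2:
            raise ValueError(f"need at least 2 trials with orientation {label!r}")
        out[label] = rec.data[idx][:, :, mask].mean(axis=(0, 2))
    return out


def _trial_prestim_maps(rec: EpochedRecording, w: float) -> np.ndarray:
    mask = rec.time_mask(-w, 0.0)
    if not mask.any():
        raise ValueError(f"pre-stimulus window [-{w}, 0) contains no samples")
    return rec.data[:, :, mask].mean(axis=2)


def _region_mask(rec: EpochedRecording, region: str) -> np.ndarray:
    if region == "all":
        return np.ones(rec.n_sensors, bool)
    mask = sensor_lobes(rec.sensor_names) == region
    if mask.sum() < 2:
        raise ValueError(f"region {region!r} maps to fewer than 2 sensors")
    return mask


def similarity_sort(rec: EpochedRecording, templates: dict, w: float,
                    region: str = "all"):
    """Split trials by which orientation template their pre-stimulus map
    correlates with more strongly (spatial Pearson over region sensors).

    Returns (group labels per trial: 'left'/'right'/'excluded', n_ties).
    Exact ties go to the 'left' group; constant (zero-variance) trial maps
    are excluded with a warning.
    """
    smask = _region_mask(rec, region)
    maps = _trial_prestim_maps(rec, w)[:, smask]
    t_l = templates["left"][smask]
    t_r = templates["right"][smask]
    labels = np.empty(rec.n_trials, dtype=object)
    n_ties = 0
    n_excluded = 0
    for i, m in enumerate(maps):
        if np.std(m) == 0 or np.std(t_l) == 0 or np.std(t_r) == 0:
            labels[i] = "excluded"
            n_excluded += 1
            continue
        cl = np.corrcoef(m, t_l)[0, 1]
        cr = np.corrcoef(m, t_r)[0, 1]
        if cl == cr:
            n_ties += 1
        labels[i] = "left" if cl >= cr else "right"
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} constant trial maps from similarity sort")
    return labels, n_ties


def sdt_measures(responses, orientations) -> SDTResult:
    """Sensitivity d' and criterion c with 'left' as signal.

    Extreme hit/false-alarm rates are handled with the log-linear rule
    (0.5 added to each cell count, 1 to each denominator) whenever a rate
    would otherwise be 0 or 1.
    """
    responses = np.asarray(responses)
    orientations = np.asarray(orientations)
    sig = orientations == "left"
    noise = orientations == "right"
    if not sig.any() or not noise.any():
        raise ValueError("both stimulus classes must be present")
    hits = np.sum((responses == "left") & sig)
    fas = np.sum((responses == "left") & noise)
    n_sig, n_noise = int(sig.sum()), int(noise.sum())
    h, fa = hits / n_sig, fas / n_noise
    corrected = h in (0.0, 1.0) or fa in (0.0, 1.0)
    if corrected:
        h = (hits + 0.5) / (n_sig + 1)
        fa = (fas + 0.5) / (n_noise + 1)
    zh, zfa = st.norm.ppf(h), st.norm.ppf(fa)
    return SDTResult(
        d_prime=float(zh - zfa),
        criterion=float(-(zh + zfa) / 2),
        hit_rate=float(h),
        fa_rate=float(fa),
        n_trials=n_sig + n_noise,
        corrected=corrected,
    )


def subject_group_criteria(rec: EpochedRecording, cfg: PrestimConfig | None = None) -> pd.DataFrame:
    """Per-(window, region) group criteria for one subject's unseen trials.

    Returns a DataFrame with columns w, region, c_left, c_right (NaN when a
    group has fewer than 2 trials or a stimulus class is absent, with a
    warning). Accepts the full recording (unseen trials are selected here).
    """
    cfg = cfg or PrestimConfig()
    if rec.meta["seen"].astype(bool).any():
        rec = rec.select_trials(~rec.meta["seen"].astype(bool).to_numpy())
    rows = []
    for w in cfg.window_lengths:
        templates = build_templates(rec, w)
        for region in cfg.regions:
            labels, _ = similarity_sort(rec, templates, w, region)
            cs = {"left": np.nan, "right": np.nan}
            for grp in ("left", "right"):
                idx = labels == grp
                if idx.sum() < 2:
                    warnings.warn(
                        f"subject {rec.meta['subject_id'].iloc[0]}: <2 trials in "
                        f"group {grp!r} for (w={w}, region={region}); excluded"
                    )
                    break
                sub = rec.meta.loc[idx]
                try:
                    cs[grp] = sdt_measures(
                        sub["response"].to_numpy(), sub["orientation"].to_numpy()
                    ).criterion
                except ValueError as err:
                    warnings.warn(str(err))
                    break
            rows.append({"w": w, "region": region,
                         "c_left": cs["left"], "c_right": cs["right"]})
    return pd.DataFrame(rows)


def aggregate_prestim(subject_tables) -> pd.DataFrame:
    """Group-level table from per-subject criteria: paired two-tailed t-test
    of c_left vs c_right across subjects per cell, BH-FDR across cells."""
    rows = []
    keys = subject_tables[0][["w", "region"]]
    for i in range(len(keys)):
        w, region = keys.iloc[i]
        cl = np.array([t["c_left"].iloc[i] for t in subject_tables], float)
        cr = np.array([t["c_right"].iloc[i] for t in subject_tables], float)
        ok = np.isfinite(cl) & np.isfinite(cr)
        n_subj = int(ok.sum())
        if n_subj >= 2:
            t_stat, p = st.ttest_rel(cl[ok], cr[ok])
        else:
            t_stat, p = np.nan, np.nan
        rows.append({
            "w": w, "region": region, "n_subjects": n_subj,
            "c_left_group": float(np.mean(cl[ok])) if n_subj else np.nan,
            "c_right_group": float(np.mean(cr[ok])) if n_subj else np.nan,
            "delta_c": float(np.mean(cl[ok] - cr[ok])) if n_subj else np.nan,
            "t": float(t_stat), "p": float(p),
        })
    table = pd.DataFrame(rows)
    valid = table["p"].notna().to_numpy()
    reject = np.zeros(len(table), bool)
    p_fdr = np.full(len(table), np.nan)
    if valid.any():
        rej, padj = bh_fdr(table.loc[valid, "p"].to_numpy(), q=0.05)
        reject[valid] = rej
        p_fdr[valid] = padj
    table["p_fdr"] = p_fdr
    table["significant"] = reject
    table.attrs["convention"] = SDTResult(0, 0, 0, 0, 0, False).convention
    return table


def run_prestim_analysis(recs, cfg: PrestimConfig | None = None) -> pd.DataFrame:
    """Full window-by-region criterion analysis over unseen trials.

    ``recs``: one (broadband) EpochedRecording per subject. For every
    (window length w, region): templates from [0, w), similarity sort over
    [-w, 0), criterion per group and subject, paired two-tailed t-test of
    the group criterion difference across subjects, then BH-FDR across all
    w x region cells. The output has one row per cell with columns
    w, region, c_left_group, c_right_group, delta_c (= c of the
    left-template-like group minus c of the right-like group; negative
    delta_c means the left-like group is more liberal toward answering
    "left"), t, p, p_fdr, significant, n_subjects.
    """
    cfg = cfg or PrestimConfig()
    if isinstance(recs, EpochedRecording):
        recs = [recs]
    return aggregate_prestim([subject_group_criteria(r, cfg) for r in recs])
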