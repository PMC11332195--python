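"""Signal detection analysis of the real-vs-generated 2AFC task.

Confidence ratings after each binary response are folded into a single
12-point ordinal scale (1 = "confident generated" ... 12 = "confident real").
Sweeping the 11 interior cutoffs of that scale traces an empirical ROC curve
per participant or pooled; its trapezoidal area (AUC) summarizes
discriminability without committing to a single criterion. d' and criterion
come from the usual equal-variance Gaussian inversion of one (hit, FA) pair.
The signal convention throughout: a *real* image is the signal, so hits are
real images called real and false alarms are generated images called real.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "SDTSummary",
    "confidence_scale",
    "empirical_roc",
    "roc_by_participant",
    "group_auc",
    "dprime",
    "auc_boot_test",
    "image_realness",
]

N_SCALE = 12  # 2 responses x 6 confidence levels


def confidence_scale(response, confidence):
    """Map (response, confidence 1-6) to the ordinal 1..12 evidence scale.

    ("generated", 6) -> 1 ... ("generated", 1) -> 6,
    ("real", 1) -> 7 ... ("real", 6) -> 12. Bijective; vectorized.
    """
    response = np.asarray(response)
    confidence = np.asarray(confidence)
    if np.any((confidence < 1) | (confidence > 6)):
        raise ValueError("confidence must lie in 1..6")
    valid = np.isin(response, ("real", "generated"))
    if not np.all(valid):
        raise ValueError(f"unknown responses: {set(np.unique(response[~valid]))}")
    scale = np.where(response == "real", 6 + confidence, 7 - confidence)
    if scale.ndim == 0:
        return int(scale)
    return scale.astype(int)


@dataclass
class ROCCurve:
    """Ordered (false-alarm, hit) points incl. (0,0) and (1,1), with AUC."""

    fa: np.ndarray
    hit: np.ndarray
    auc: float
    n_signal: int
    n_noise: int
    labels: dict = field(default_factory=dict)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fa, self.hit])


@dataclass
class SDTSummary:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    correction: str | None


def _scale_column(trials: pd.DataFrame) -> np.ndarray:
    if "scale" in trials.columns:
        return trials["scale"].to_numpy(int)
    return confidence_scale(trials["response"].to_numpy(), trials["confidence"].to_numpy())


def empirical_roc(trials: pd.DataFrame, signal_label: str = "real",
                  labels: dict | None = None) -> ROCCurve:
    """Empirical ROC from the 12-point ordinal scale.

    For each cutoff k in 1..11: hit(k) = P(scale > k | signal),
    fa(k) = P(scale > k | noise); endpoints (0,0) and (1,1) appended and the
    AUC computed by the trapezoid rule.
    """
    scale = _scale_column(trials)
    is_signal = (trials["condition"] == signal_label).to_numpy()
    n_signal = int(is_signal.sum())
    n_noise = int(len(trials) - n_signal)
    if n_signal == 0 or n_noise == 0:
        raise ValueError("empirical_roc needs both signal and noise trials")
    cutoffs = np.arange(1, N_SCALE)
    hit = (scale[is_signal][:, None] > cutoffs).mean(axis=0)
    fa = (scale[~is_signal][:, None] > cutoffs).mean(axis=0)
    fa_pts = np.concatenate([[0.0], np.sort(fa), [1.0]])
    hit_pts = np.concatenate([[0.0], np.sort(hit), [1.0]])
    auc = float(np.trapezoid(hit_pts, fa_pts))
    return ROCCurve(fa_pts, hit_pts, auc, n_signal, n_noise, labels or {})


def roc_by_participant(trials: pd.DataFrame, signal_label: str = "real") -> dict:
    return {p: empirical_roc(g, signal_label, labels={"participant": p})
            for p, g in trials.groupby("participant")}


def group_auc(trials: pd.DataFrame, signal_label: str = "real", pooled: bool = False) -> float:
    """Group AUC: unweighted mean of per-participant AUCs (default), or the
    AUC of all trials pooled."""
    if pooled:
        return empirical_roc(trials, signal_label).auc
    curves = roc_by_participant(trials, signal_label)
    return float(np.mean([c.auc for c in curves.values()]))


def dprime(hit_rate: float, fa_rate: float, n_signal: int | None = None,
           n_noise: int | None = None, correction: str | None = "loglinear") -> SDTSummary:
    """Equal-variance Gaussian d' and criterion from one (hit, FA) pair.

    d' = Phi^-1(hit) - Phi^-1(fa); c = -(Phi^-1(hit) + Phi^-1(fa)) / 2.
    Extreme rates (0 or 1) are undefined without a correction:
    'loglinear' maps rate -> (count + 0.5) / (n + 1); 'clip_1_over_2N' clips
    into [1/(2n), 1 - 1/(2n)]. Both need the trial counts.
    """
    for name, rate in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if correction is not None and (n_signal is None or n_noise is None):
        raise ValueError(f"correction {correction!r} requires n_signal and n_noise")
    if correction is None:
        if hit_rate in (0.0, 1.0) or fa_rate in (0.0, 1.0):
            raise ValueError("rate of 0 or 1 is undefined without a correction")
        h, f = hit_rate, fa_rate
    elif correction == "loglinear":
        h = (hit_rate * n_signal + 0.5) / (n_signal + 1)
        f = (fa_rate * n_noise + 0.5) / (n_noise + 1)
    elif correction == "clip_1_over_2N":
        h = float(np.clip(hit_rate, 1 / (2 * n_signal), 1 - 1 / (2 * n_signal)))
        f = float(np.clip(fa_rate, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise)))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    zh, zf = norm.ppf(h), norm.ppf(f)
    return SDTSummary(hit_rate=h, fa_rate=f, d_prime=float(zh - zf),
                      criterion=float(-(zh + zf) / 2), correction=correction)


def _scale_counts(trials: pd.DataFrame, signal_label: str = "real"):
    """Per-participant counts over the 12-point scale, (signal, noise) each
    shaped (n_participants, 12). The empirical ROC and its AUC are functions
    of these counts only, so case resampling of trials within (participant,
    condition) is equivalent to multinomial resampling of the counts."""
    scale = _scale_column(trials)
    is_signal = (trials["condition"] == signal_label).to_numpy()
    participants = np.unique(trials["participant"])
    p_idx = pd.Series(np.arange(len(participants)), index=participants)
    rows = p_idx[trials["participant"]].to_numpy()
    sig = np.zeros((len(participants), N_SCALE), dtype=np.int64)
    noi = np.zeros((len(participants), N_SCALE), dtype=np.int64)
    np.add.at(sig, (rows[is_signal], scale[is_signal] - 1), 1)
    np.add.at(noi, (rows[~is_signal], scale[~is_signal] - 1), 1)
    return sig, noi


def _auc_from_counts(sig: np.ndarray, noi: np.ndarray, pooled: bool) -> float:
    """Trapezoidal AUC from scale counts; participant mean or pooled."""
    if pooled:
        sig = sig.sum(axis=0, keepdims=True)
        noi = noi.sum(axis=0, keepdims=True)
    ok = (sig.sum(axis=1) > 0) & (noi.sum(axis=1) > 0)
    sig, noi = sig[ok], noi[ok]
    # P(scale > k) for cutoffs k = 1..11, plus endpoints
    hit = np.cumsum(sig[:, ::-1], axis=1)[:, ::-1][:, 1:] / sig.sum(axis=1, keepdims=True)
    fa = np.cumsum(noi[:, ::-1], axis=1)[:, ::-1][:, 1:] / noi.sum(axis=1, keepdims=True)
    zeros = np.zeros((len(hit), 1))
    ones = np.ones((len(hit), 1))
    hit = np.hstack([zeros, np.sort(hit, axis=1), ones])
    fa = np.hstack([zeros, np.sort(fa, axis=1), ones])
    auc = np.trapezoid(hit, fa, axis=1)
    return float(auc.mean())


def auc_boot_test(trials_a: pd.DataFrame, trials_b: pd.DataFrame,
                  n_boot: int = 2000, seed: int = 0, pooled: bool = False,
                  stratified: bool = True) -> dict:
    """Bootstrap test of the AUC difference between two trial sets (e.g. the
    50 ms vs 500 ms conditions), two-sided alternative of nonzero difference.

    Stratified case resampling (default): participants with replacement,
    then trials with replacement within (participant, condition) —
    implemented as multinomial resampling of per-participant scale counts,
    which is exactly equivalent for the empirical ROC. `stratified=False`
    resamples trial rows flat instead. The two-sided p uses add-one
    smoothing on the smaller tail of the bootstrap difference distribution
    around zero, capped at 1; the CI is the 2.5/97.5 percentile interval.
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unstable p-values")
    counts = [_scale_counts(t) for t in (trials_a, trials_b)]
    auc_a = _auc_from_counts(*counts[0], pooled=pooled)
    auc_b = _auc_from_counts(*counts[1], pooled=pooled)
    # each table gets a stream derived from its own counts, so the test is
    # exactly antisymmetric under swapping A and B, and identical inputs
    # give a degenerate difference distribution (p = 1)
    rngs = [np.random.default_rng(np.random.SeedSequence(
        [seed, 6, int.from_bytes(hashlib.sha256(sig.tobytes() + noi.tobytes()).digest()[:4], "big")]))
        for sig, noi in counts]

    def one_boot(rng, sig, noi):
        n_p = sig.shape[0]
        if stratified:
            pick = rng.integers(0, n_p, n_p)
            sig_p, noi_p = sig[pick], noi[pick]
            new_sig = np.vstack([rng.multinomial(s.sum(), s / s.sum()) if s.sum() else s
                                 for s in sig_p])
            new_noi = np.vstack([rng.multinomial(s.sum(), s / s.sum()) if s.sum() else s
                                 for s in noi_p])
        else:
            # flat trial resampling, participant labels kept
            tot = np.vstack([sig, noi]).sum()
            flat = np.concatenate([sig.ravel(), noi.ravel()])
            draw = rng.multinomial(tot, flat / tot)
            new_sig = draw[: sig.size].reshape(sig.shape)
            new_noi = draw[sig.size:].reshape(noi.shape)
        return _auc_from_counts(new_sig, new_noi, pooled=pooled)

    diffs = np.empty(n_boot)
    for i in range(n_boot):
        diffs[i] = one_boot(rngs[0], *counts[0]) - one_boot(rngs[1], *counts[1])
    below = int(np.sum(diffs <= 0))
    above = int(np.sum(diffs >= 0))
    p = min(1.0, 2.0 * (min(below, above) + 1) / (n_boot + 1))
    ci = tuple(np.percentile(diffs, [2.5, 97.5]))
    return {"auc_a": auc_a, "auc_b": auc_b, "diff": auc_a - auc_b,
            "p_value": p, "ci": ci, "n_boot": n_boot}


def image_realness(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-image realness: the mean binary response (real=1, generated=0) an
    image received, separately for each presentation duration.

    Image x duration cells with no trials come back as missing and are
    logged. Returns columns image_id, duration, realness, n_trials.
    """
    t = trials.copy()
    t["resp_real"] = (t["response"] == "real").astype(float)
    agg = (t.groupby(["image_id", "duration"])["resp_real"]
           .agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "realness", "size": "n_trials"}))
    full = pd.MultiIndex.from_product(
        [t["image_id"].unique(), sorted(t["duration"].unique())],
        names=["image_id", "duration"]).to_frame(index=False)
    out = full.merge(agg, on=["image_id", "duration"], how="left")
    missing = out["realness"].isna()
    if missing.any():
        logger.warning("image_realness: %d image x duration cells without trials",
                       int(missing.sum()))
        out.loc[missing, "n_trials"] = 0
    out["n_trials"] = out["n_trials"].astype(int)
    return out
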