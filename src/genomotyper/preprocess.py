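"""Probe QC and replicate reduction.

Two probe filters are provided:

* self-self background filter — a probe is unreliable when its mean raw
  signal across the self-versus-self replicates is not strictly above
  ``mean(background) + k * SD(background)`` in *either* channel (default
  k = 3; the rule operationalizes "not well above background").
* per-probe one-way ANOVA across strains with Bonferroni adjustment
  ``p_adj = min(1, p * G)``.  Whether "significant" probes are kept or
  dropped is a policy choice (see :func:`anova_probe_filter`); the default
  pipeline applies no ANOVA filter because on presence/absence data a
  strain-effect test removes exactly the invariant core genes.

Replicates are reduced by the arithmetic mean over non-missing spots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arrayio import LogRatioTensor
from .errors import ConfigError

logger = logging.getLogger(__name__)

ANOVA_POLICIES = ("keep_significant", "drop_significant", "none")


@dataclass
class ProbeQCReport:
    """Per-probe QC flags and the parameters that produced them.

    ``kept = ~low_signal_selfself & ~anova_fail`` under the default policy;
    flag counts plus the kept count always reconcile to the probe total.
    """

    probe_ids: list[str]
    low_signal_selfself: np.ndarray          # bool per probe
    anova_fail: np.ndarray                   # bool per probe
    params: dict = field(default_factory=dict)
    pvalues: np.ndarray | None = None        # Bonferroni-adjusted, if ANOVA ran

    @property
    def kept(self) -> np.ndarray:
        return ~self.low_signal_selfself & ~self.anova_fail

    def counts(self) -> dict:
        return {
            "n_probes": len(self.probe_ids),
            "n_low_signal_selfself": int(self.low_signal_selfself.sum()),
            "n_anova_fail": int(self.anova_fail.sum()),
            "n_both_flags": int((self.low_signal_selfself & self.anova_fail).sum()),
            "n_kept": int(self.kept.sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probe_ids,
            "low_signal_selfself": self.low_signal_selfself,
            "anova_fail": self.anova_fail,
            "kept": self.kept,
        }).set_index("probe_id")

    def merge(self, other: "ProbeQCReport") -> "ProbeQCReport":
        """OR the flags of two reports computed on the same probe set."""
        if self.probe_ids != other.probe_ids:
            raise ConfigError("cannot merge QC reports over different probe sets")
        return ProbeQCReport(
            probe_ids=self.probe_ids,
            low_signal_selfself=self.low_signal_selfself | other.low_signal_selfself,
            anova_fail=self.anova_fail | other.anova_fail,
            params={**self.params, **other.params},
            pvalues=other.pvalues if other.pvalues is not None else self.pvalues)


def _empty_report(probe_ids: list[str], **params) -> ProbeQCReport:
    n = len(probe_ids)
    return ProbeQCReport(list(probe_ids), np.zeros(n, bool), np.zeros(n, bool),
                         params=dict(params))


def filter_selfself_background(selfself: LogRatioTensor, k: float = 3.0) -> ProbeQCReport:
    """Flag probes whose self-self raw signal is not well above background.

    A probe is kept only if its replicate-mean signal exceeds
    ``mean(background) + k*SD(background)`` strictly, in both channels.
    Without raw signals the stage is skipped with a warning and every probe
    is marked kept.
    """
    if selfself.raw is None:
        warnings.warn("self-self arrays carry no raw signals; background QC skipped")
        logger.warning("background QC skipped: no raw signals")
        return _empty_report(selfself.probe_ids, background_k=k, skipped=True)
    raw = selfself.raw
    bg = raw["background"].to_numpy(float)
    threshold = bg.mean() + k * bg.std(ddof=1)
    means = raw.groupby("probe_id", sort=False)[["test_signal", "ref_signal"]].mean()
    means = means.reindex(selfself.probe_ids)
    low = ~((means["test_signal"] > threshold) & (means["ref_signal"] > threshold))
    low = low.fillna(True).to_numpy(bool)
    report = _empty_report(selfself.probe_ids, background_k=k,
                           background_threshold=float(threshold))
    report.low_signal_selfself = low
    logger.info("background QC: %d/%d probes flagged low-signal",
                int(low.sum()), len(low))
    return report


def anova_probe_filter(tensor: LogRatioTensor, alpha: float = 0.01,
                       correction: str = "bonferroni",
                       policy: str = "keep_significant") -> ProbeQCReport:
    """Per-probe one-way fixed-effects ANOVA of log-ratios across strains.

    A probe is *retained* iff its Bonferroni-adjusted p-value
    (``min(1, p*G)``, G = probes tested) is below ``alpha``.  ``policy``
    maps retention to the fail flag: ``keep_significant`` fails
    non-significant probes (the published procedure's wording),
    ``drop_significant`` the reverse, ``none`` fails nothing but still
    records p-values.

    Degenerate probes: no variation at all -> p = 1; zero within-group
    variance with a between-group difference -> p = 0.
    """
    if policy not in ANOVA_POLICIES:
        raise ConfigError(f"unknown ANOVA policy {policy!r}")
    if correction != "bonferroni":
        raise ConfigError(f"unsupported correction {correction!r}")
    x = tensor.values
    G, S, R = x.shape
    if S < 2 or R < 2:
        raise ConfigError("ANOVA filter needs >=2 strains with >=2 replicates")

    with np.errstate(invalid="ignore"):
        ni = np.sum(~np.isnan(x), axis=2)                      # (G,S)
        mi = np.nanmean(x, axis=2)                             # strain means
        ntot = ni.sum(axis=1)
        grand = np.nansum(np.where(np.isnan(mi), 0, mi * ni), axis=1) / ntot
        ssb = np.nansum(ni * (mi - grand[:, None]) ** 2, axis=1)
        ssw = np.nansum((x - mi[:, :, None]) ** 2, axis=(1, 2))
    dfb = S - 1
    dfw = ntot - S
    scale = np.maximum(1.0, np.nanmax(np.abs(x)) if np.isfinite(x).any() else 1.0)
    tol = 1e-12 * scale ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / np.maximum(dfw, 1))
        p = stats.f.sf(F, dfb, np.maximum(dfw, 1))
    degenerate = ssw <= tol
    p = np.where(degenerate & (ssb > tol), 0.0, p)
    p = np.where(degenerate & (ssb <= tol), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    p_adj = np.minimum(1.0, p * G)
    retained = p_adj < alpha
    if policy == "keep_significant":
        fail = ~retained
    elif policy == "drop_significant":
        fail = retained
    else:
        fail = np.zeros(G, bool)
    report = _empty_report(tensor.probe_ids, alpha=alpha, correction=correction,
                           anova_policy=policy, n_tested=G)
    report.anova_fail = fail
    report.pvalues = p_adj
    logger.info("ANOVA filter (%s): %d/%d probes retained at alpha=%g",
                policy, int(retained.sum()), G, alpha)
    return report


@dataclass
class RatioMatrix:
    """Replicate-averaged log-ratios: one value per probe per strain."""

    probe_ids: list[str]
    strains: list[str]
    values: np.ndarray                 # (probes, strains), NaN = missing
    reference: str | None = None
    outgroups: list[str] = field(default_factory=list)
    n_missing_spots: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=self.strains)

    def column(self, strain: str) -> np.ndarray:
        return self.values[:, self.strains.index(strain)]


def average_replicates(tensor: LogRatioTensor) -> RatioMatrix:
    """Arithmetic mean over non-missing replicates per probe per strain.

    A probe/strain cell with zero valid replicates stays NaN and the
    missing-spot count is recorded.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(tensor.values, axis=2)
    n_missing = int(np.isnan(tensor.values).sum())
    return RatioMatrix(list(tensor.probe_ids), list(tensor.strains), means,
                       tensor.reference, list(tensor.outgroups), n_missing)
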