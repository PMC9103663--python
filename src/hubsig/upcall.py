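"""Per-pair upregulation calling from paired tumor/control counts.

Each tumor sample is compared only against its own matched control: counts
are normalized by coding-sequence length (with a CPM-like library factor),
the control log-expression is subtracted from the tumor's, and genes whose
log differential exceeds a per-pair critical value are called upregulated.
The default critical value is the parametric normal-tail rule
``mean + z(1 - alpha) * sd`` on that pair's log-differential distribution at
alpha = 0.025; an empirical-quantile rule is available as a plug-in
alternative, and the two are not claimed to coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthcohort import SampleProfile

__all__ = [
    "PairedExpression",
    "UpregulationCall",
    "length_normalize",
    "log_differential",
    "critical_threshold",
    "call_upregulated",
    "call_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedExpression:
    """One tumor–control pair: counts and coding-sequence lengths per gene."""

    pair_id: str
    tumor: pd.Series
    control: pd.Series
    lengths: pd.Series

    def __post_init__(self):
        self.tumor = pd.Series(self.tumor, dtype=float)
        self.control = pd.Series(self.control, dtype=float)
        self.lengths = pd.Series(self.lengths, dtype=float)
        if set(self.tumor.index) != set(self.control.index):
            raise ValueError("tumor and control gene sets differ")
        if (self.lengths.reindex(self.tumor.index) <= 0).any():
            raise ValueError("coding-sequence lengths must be positive")


@dataclass
class UpregulationCall:
    pair_id: str
    log_diff: pd.Series
    threshold: float
    upregulated: frozenset[str]


def length_normalize(
    counts: pd.Series, lengths: pd.Series, scale: float | str = "cpm"
) -> pd.Series:
    """Counts per unit coding-sequence length.

    ``scale="cpm"`` rescales the length-normalized values to sum to 1e6 per
    sample (reads-per-kilobase-like within-sample normalization); a numeric
    ``scale`` multiplies the raw count/length rates instead (1.0 = none).
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for {len(missing)} genes, e.g. {list(missing[:3])}")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("lengths must be strictly positive")
    rates = counts / lengths
    if scale == "cpm":
        total = rates.sum()
        if total > 0:
            rates = rates * (1e6 / total)
        return rates
    return rates * float(scale)


def log_differential(
    tumor_rates: pd.Series, control_rates: pd.Series, pseudocount: float = 0.5
) -> pd.Series:
    """log2((tumor + c) / (control + c)); antisymmetric under swap."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    tumor_rates = pd.Series(tumor_rates, dtype=float)
    control_rates = pd.Series(control_rates, dtype=float).reindex(tumor_rates.index)
    if control_rates.isna().any():
        raise ValueError("tumor and control gene sets differ")
    return np.log2((tumor_rates + pseudocount) / (control_rates + pseudocount))


def critical_threshold(
    values: pd.Series | np.ndarray, alpha: float = 0.025, rule: str = "normal"
) -> float:
    """Per-pair critical value above which a gene is called upregulated.

    rule="normal":  mean + z(1 - alpha) * sd of the log-differential
    distribution (sd with n-1 denominator). Falls back to the empirical
    quantile, with a warning, if the distribution is degenerate.
    rule="quantile": empirical (1 - alpha) quantile.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError(f"need >= 30 finite values, got {x.size}")
    if rule == "quantile":
        return float(np.quantile(x, 1.0 - alpha))
    if rule != "normal":
        raise ValueError(f"unknown rule {rule!r}")
    sd = float(np.std(x, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        warnings.warn(
            "degenerate log-differential distribution; falling back to "
            "empirical quantile",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.quantile(x, 1.0 - alpha))
    return float(np.mean(x) + stats.norm.ppf(1.0 - alpha) * sd)


def call_upregulated(
    pair: PairedExpression,
    alpha: float = 0.025,
    pseudocount: float = 0.5,
    rule: str = "normal",
    scale: float | str = "cpm",
) -> UpregulationCall:
    """Length-normalize, take the log differential, threshold: one pair's call.

    The upregulated set is exactly the genes whose log differential strictly
    exceeds the pair's critical value.
    """
    t = length_normalize(pair.tumor, pair.lengths, scale=scale)
    c = length_normalize(pair.control, pair.lengths, scale=scale)
    diff = log_differential(t, c, pseudocount=pseudocount)
    thr = critical_threshold(diff, alpha=alpha, rule=rule)
    up = frozenset(diff.index[diff > thr])
    return UpregulationCall(pair.pair_id, diff, thr, up)


def call_cohort(
    tumor: pd.DataFrame,
    control: pd.DataFrame,
    lengths: pd.Series,
    cancer_type: str = "SYN",
    class_label: str = "H",
    gene_universe: set[str] | None = None,
    alpha: float = 0.025,
    pseudocount: float = 0.5,
    rule: str = "normal",
) -> tuple[list[UpregulationCall], list[SampleProfile]]:
    """Call every pair (column) of a paired count table.

    Genes outside ``gene_universe`` (e.g. the interactome's coding-sequence
    set) are dropped before calling; the dropped count is logged.
    """
    if gene_universe is not None:
        keep = [g for g in tumor.index if g in gene_universe]
        dropped = len(tumor.index) - len(keep)
        if dropped:
            logger.info("dropping %d genes outside the gene universe", dropped)
        tumor, control = tumor.loc[keep], control.loc[keep]
        lengths = lengths.loc[keep]
    calls, profiles = [], []
    for pair_id in tumor.columns:
        pair = PairedExpression(pair_id, tumor[pair_id], control[pair_id], lengths)
        call = call_upregulated(pair, alpha=alpha, pseudocount=pseudocount, rule=rule)
        calls.append(call)
        profiles.append(
            SampleProfile(pair_id, cancer_type, class_label, call.upregulated)
        )
    return calls, profiles
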