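"""Output specialization of presynaptic neurons: single-type biased vs
multi-target.

For each presynaptic neuron with output onto descending neurons, outputs are
pooled by postsynaptic DN type label and summarised by three statistics: the
fraction of total output strength onto the dominant (most strongly targeted)
type, the Shannon entropy (bits) of the type-level strength distribution, and
the strongest off-target type's summed strength.  A dataset-specific cutoff on
the dominant fraction is discovered by minimising the within-class variance of
the split (Otsu's criterion), and a neuron is called single-type biased when
its dominant fraction reaches the cutoff and its strongest off-target type
stays below a synapse cap (default 15 — off-target strength of 15 or more
disqualifies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectome import ConnectomeTable, NeuronClass

__all__ = [
    "OutputProfile",
    "ThresholdResult",
    "SpecializationRecord",
    "output_profile",
    "all_profiles",
    "find_threshold",
    "classify_all",
    "exclusive_per_dn",
]


@dataclass
class OutputProfile:
    neuron_id: int
    per_target_type_strength: dict[str, float]
    total_out_strength: float
    dominant_type: str
    dominant_fraction: float
    entropy: float  # bits
    off_target_max: float
    dominant_tie: bool = False


@dataclass
class ThresholdResult:
    cutoff: float
    error_curve: dict[float, float]
    ks_statistic: float
    ks_p: float


@dataclass
class SpecializationRecord:
    neuron_id: int
    profile: OutputProfile
    call: str  # "single_type_biased" | "multi_target"
    exclusion_reason: str | None = None


def _entropy_bits(strengths: np.ndarray) -> float:
    p = strengths / strengths.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def output_profile(table: ConnectomeTable, neuron_id: int) -> OutputProfile:
    """Profile one presynaptic neuron's output onto DN types.

    Strengths are grouped by the postsynaptic DN type label (all copies of a
    type pooled); entropy is over the strength proportions, base 2.  Ties for
    the dominant type break lexicographically and are flagged.
    """
    by_id = table.neuron_by_id()
    per_type: dict[str, float] = {}
    for c in table.connections:
        if c.pre_id != neuron_id:
            continue
        post = by_id[c.post_id]
        if post.neuron_class is not NeuronClass.DN:
            continue
        per_type[post.type_label] = per_type.get(post.type_label, 0.0) + c.weight
    if not per_type:
        raise ValueError(f"neuron {neuron_id} has no output onto DNs")
    return _profile_from_map(neuron_id, per_type)


def _profile_from_map(neuron_id: int, per_type: dict[str, float]) -> OutputProfile:
    total = sum(per_type.values())
    best = max(per_type.values())
    winners = sorted(t for t, s in per_type.items() if s == best)
    dominant = winners[0]
    off = [s for t, s in per_type.items() if t != dominant]
    return OutputProfile(
        neuron_id=neuron_id,
        per_target_type_strength=dict(sorted(per_type.items())),
        total_out_strength=total,
        dominant_type=dominant,
        dominant_fraction=best / total,
        entropy=_entropy_bits(np.array(list(per_type.values()), dtype=float)),
        off_target_max=max(off) if off else 0.0,
        dominant_tie=len(winners) > 1,
    )


def all_profiles(table: ConnectomeTable) -> list[OutputProfile]:
    """Profiles for every neuron with at least one DN-targeting output."""
    by_id = table.neuron_by_id()
    per_neuron: dict[int, dict[str, float]] = {}
    for c in table.connections:
        post = by_id[c.post_id]
        if post.neuron_class is not NeuronClass.DN:
            continue
        d = per_neuron.setdefault(c.pre_id, {})
        d[post.type_label] = d.get(post.type_label, 0.0) + c.weight
    return [_profile_from_map(nid, d) for nid, d in sorted(per_neuron.items())]


def find_threshold(fractions) -> ThresholdResult:
    """Discover the cutoff separating multi-target from single-type biased
    neurons on the dominant-fraction distribution.

    Candidate cutoffs are midpoints between consecutive distinct observed
    fractions; the error parameter is Otsu's within-class variance
    w₀σ₀² + w₁σ₁², minimised over candidates that leave both sides nonempty.
    A two-sample Kolmogorov–Smirnov test between the split groups is reported.
    """
    x = np.asarray(sorted(fractions), dtype=float)
    if len(x) < 10:
        raise ValueError(f"need at least 10 fractions, got {len(x)}")
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("degenerate dominant-fraction distribution: all values equal")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    curve: dict[float, float] = {}
    best_c, best_err = None, math.inf
    for c in candidates:
        lo = x[x < c]
        hi = x[x >= c]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0 = len(lo) / len(x)
        w1 = len(hi) / len(x)
        err = w0 * lo.var() + w1 * hi.var()
        curve[float(c)] = float(err)
        if err < best_err:
            best_err, best_c = err, float(c)
    lo = x[x < best_c]
    hi = x[x >= best_c]
    ks = stats.ks_2samp(lo, hi)
    return ThresholdResult(
        cutoff=best_c,
        error_curve=curve,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


def classify_all(
    table: ConnectomeTable, cutoff: float, off_target_cap: float = 15.0
) -> list[SpecializationRecord]:
    """Call every DN-targeting presynaptic neuron.

    single_type_biased iff dominant_fraction ≥ cutoff and the strongest
    off-target type carries fewer than ``off_target_cap`` synapses; otherwise
    multi_target, with the disqualifying rule recorded.
    """
    records: list[SpecializationRecord] = []
    for prof in all_profiles(table):
        if prof.dominant_fraction < cutoff:
            records.append(SpecializationRecord(prof.neuron_id, prof, "multi_target", "below_cutoff"))
        elif prof.off_target_max >= off_target_cap:
            records.append(SpecializationRecord(prof.neuron_id, prof, "multi_target", "off_target_cap"))
        else:
            records.append(SpecializationRecord(prof.neuron_id, prof, "single_type_biased"))
    return records


def exclusive_per_dn(records) -> dict[str, int]:
    """Count single-type-biased neurons per dominant DN type."""
    out: dict[str, int] = {}
    for r in records:
        if r.call == "single_type_biased":
            t = r.profile.dominant_type
            out[t] = out.get(t, 0) + 1
    return dict(sorted(out.items()))
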