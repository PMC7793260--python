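"""Acceptor FRET efficiency (Ef_A), replicate statistics and distance conversion.

Ef_A is the sensitized acceptor emission normalized to the directly excited
acceptor emission in the donor-excitation channel:

    F_direct    = rho * A_587          (rho: crosstalk ratio from the basis)
    F_sensitized = A_541 - F_direct
    Ef_A(%)     = 100 * kappa * F_sensitized / F_direct

where ``A_541`` / ``A_587`` are the fitted acceptor-shaped amplitudes under
donor / acceptor excitation and ``kappa`` is the extinction-coefficient ratio
of acceptor to donor at the donor excitation wavelength.  With the default
``kappa = 1`` the value is an instrument-relative efficiency; for a sample
whose acceptors are all complexed with donors it estimates
(true transfer efficiency) x (fraction of acceptors in complex).

Distances follow the Foerster relation ``E = 1 / (1 + (r/R0)^6)`` with
``R0 = 6.4 nm`` for the mCherry-mKO pair.

Ef_A is deliberately NOT floored at zero: at noise level a true-zero sample
scatters symmetrically around 0, and clipping would bias every negative
control upward (the reported ``sensitized`` amplitude, a physical quantity,
is floored; a ``negative_sensitized`` QC flag marks such samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    InsufficientReplicatesError,
    UndefinedEfficiencyError,
)
from .unmixing import ReferenceBasis, UnmixResult

#: Foerster distance of the mCherry(acceptor)/mKO(donor) pair, nm.
DEFAULT_R0_NM = 6.4
#: Mean rise per residue along a transmembrane alpha-helix, nm.
HELIX_RISE_NM_PER_RESIDUE = 0.15
#: amplitude below this multiple of the fit's residual scale gets a QC flag
LOW_SIGNAL_SNR = 3.0


@dataclass(frozen=True)
class FretCalibration:
    """Calibration constants: kappa (extinction ratio at donor excitation) and R0."""

    epsilon_ratio_kappa: float = 1.0
    r0_nm: float = DEFAULT_R0_NM

    def __post_init__(self):
        if self.epsilon_ratio_kappa <= 0:
            raise DomainError("epsilon_ratio_kappa must be > 0")
        if self.r0_nm <= 0:
            raise DomainError("r0_nm must be > 0")


@dataclass
class FretResult:
    """Per-sample acceptor FRET efficiency with its intermediate amplitudes."""

    sample_id: str
    acceptor_total_587: float
    acceptor_shaped_541: float
    direct_acceptor_541: float
    sensitized: float
    efa: float  # percent
    donor_amplitude_541: float
    replicate: int = 1
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class ReplicateSummary:
    group: str
    mean_efa: float
    sd: float
    n: int
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    t_statistic: float
    df: int
    p_value: float

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def compute_efa(
    u541: UnmixResult,
    u587: UnmixResult,
    basis: ReferenceBasis,
    cal: FretCalibration = FretCalibration(),
) -> FretResult:
    """Combine the two-channel unmix results of one sample into Ef_A (%).

    Raises :class:`UndefinedEfficiencyError` when no directly excited acceptor
    signal is present (no acceptor in the sample).
    """
    if u541.sample_id != u587.sample_id:
        raise DomainError(
            f"channel results belong to different samples: {u541.sample_id!r} vs {u587.sample_id!r}"
        )
    rho = basis.crosstalk_rho
    if not np.isfinite(rho):
        raise DomainError("basis crosstalk ratio is not finite")
    a587 = u587.amplitudes["acceptor"]
    a541 = u541.amplitudes["acceptor"]
    donor = u541.amplitudes.get("donor", 0.0)
    direct = rho * a587
    if direct <= 0:
        raise UndefinedEfficiencyError(
            f"{u541.sample_id}: no directly excited acceptor signal (rho*A587 = {direct:g})"
        )
    raw_sens = a541 - direct
    flags = []
    if raw_sens < 0:
        flags.append("negative_sensitized")
    if donor < LOW_SIGNAL_SNR * u541.residual_scale:
        flags.append("low_donor_signal")
    if a587 < LOW_SIGNAL_SNR * u587.residual_scale:
        flags.append("low_acceptor_signal")
    sens = max(0.0, raw_sens)
    efa = 100.0 * cal.epsilon_ratio_kappa * raw_sens / direct
    return FretResult(
        sample_id=u541.sample_id,
        acceptor_total_587=a587,
        acceptor_shaped_541=a541,
        direct_acceptor_541=direct,
        sensitized=sens,
        efa=efa,
        donor_amplitude_541=donor,
        replicate=u541.replicate,
        qc_flags=flags,
    )


def summarize_replicates(results: list[FretResult] | list[float], group: str) -> ReplicateSummary:
    """Mean and sample SD (ddof=1) of Ef_A over biological replicates."""
    if not results:
        raise InsufficientReplicatesError(f"group {group!r}: no replicates")
    values = np.array(
        [r.efa if isinstance(r, FretResult) else float(r) for r in results], dtype=float
    )
    n = values.size
    flags = []
    if n >= 2:
        sd = float(values.std(ddof=1))
    else:
        sd = 0.0
        flags.append("single_replicate_sd_undefined")
    return ReplicateSummary(group=group, mean_efa=float(values.mean()), sd=sd, n=n, qc_flags=flags)


def compare_groups(
    a: list[float], b: list[float], group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Two-sided two-sample Student's t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError("each group needs n >= 2 for a t-test")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate pooled SE: identical constants are indistinguishable,
        # different constants are separated with certainty
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        t_statistic=float(t),
        df=int(a.size + b.size - 2),
        p_value=float(p),
    )


def efficiency_to_distance(efa_fraction: float, cal: FretCalibration = FretCalibration()) -> float:
    """Invert the Foerster relation: r = R0 * ((1 - E) / E)^(1/6), E as a fraction."""
    e = float(efa_fraction)
    if not 0.0 < e < 1.0:
        raise DomainError(f"efficiency must be in (0, 1), got {e}")
    return cal.r0_nm * ((1.0 - e) / e) ** (1.0 / 6.0)


def distance_to_efficiency(r_nm: float, cal: FretCalibration = FretCalibration()) -> float:
    """E = 1 / (1 + (r/R0)^6)."""
    r = float(r_nm)
    if r <= 0:
        raise DomainError(f"distance must be > 0, got {r}")
    return 1.0 / (1.0 + (r / cal.r0_nm) ** 6)


def helix_rise_bound(
    delta_residues: int, rise_nm_per_residue: float = HELIX_RISE_NM_PER_RESIDUE
) -> float:
    """Maximal fluorophore-distance change from shortening a transmembrane
    helix by ``delta_residues`` residues."""
    if delta_residues < 0 or rise_nm_per_residue < 0:
        raise DomainError("delta_residues and rise must be >= 0")
    return delta_residues * rise_nm_per_residue
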