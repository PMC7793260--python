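"""Per-experiment reference basis construction and nonnegative spectral unmixing.

Each measured spectrum is modelled as a nonnegative linear combination of
fixed component *shapes* measured in the same experiment:

* cellular autofluorescence background (empty-cell reference),
* donor emission (mKO-like fusion, donor-excitation channel only),
* acceptor emission (mCherry-like fusion, both channels).

Sensitized emission is spectrally identical to directly excited acceptor
emission, so it is deliberately NOT a separate basis column (two identical
columns would be perfectly collinear); it is isolated arithmetically in
:mod:`fretpg.fret_quant` using the direct-excitation crosstalk ratio ``rho``
measured on the acceptor-only reference.

Amplitudes are fitted by nonnegative least squares: they represent
fluorophore/background abundances, and the constraint prevents unphysical
compensation between the strongly overlapping donor/acceptor shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .errors import (
    CollinearityError,
    DegenerateReferenceError,
    UnderdeterminedError,
    WeakReferenceError,
)
from .spectra_io import EmissionSpectrum, require_same_grid

COND_WARN = 1e4
COND_FAIL = 1e6
#: a reference shape must peak at least this many residual-noise MADs above zero
WEAK_REFERENCE_SNR = 3.0
#: fraction of negative points after buffer subtraction that triggers a QC flag
NEGATIVE_FLAG_FRACTION = 0.05


def noise_mad(y: np.ndarray) -> float:
    """Robust per-point noise scale from first differences (MAD * 1.4826 / sqrt(2))."""
    d = np.diff(np.asarray(y, dtype=float))
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def subtract_buffer(sample: EmissionSpectrum, buffer: EmissionSpectrum) -> EmissionSpectrum:
    """Pointwise buffer (PBS) subtraction.

    Negative values are retained (they are noise); a QC flag is recorded in
    the metadata when more than 5% of points go negative.
    """
    require_same_grid(sample, buffer)
    diff = sample.intensities - buffer.intensities
    frac_neg = float(np.mean(diff < 0)) if diff.size else 0.0
    meta = {"buffer_subtracted": "true"}
    if frac_neg > NEGATIVE_FLAG_FRACTION:
        meta["qc_negative_fraction"] = f"{frac_neg:.3f}"
    return sample.with_intensities(diff, **meta)


def subtract_background_reference(
    ref: EmissionSpectrum, empty_cell: EmissionSpectrum
) -> EmissionSpectrum:
    """Subtract the (buffer-subtracted) empty-cell autofluorescence from a
    fluorophore reference and clip at zero for shape extraction."""
    require_same_grid(ref, empty_cell)
    diff = np.clip(ref.intensities - empty_cell.intensities, 0.0, None)
    return ref.with_intensities(diff, background_subtracted="true")


def _unit_shape(y: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    y = np.asarray(y, dtype=float)
    norm = float(np.linalg.norm(y))
    if norm == 0.0 or not np.isfinite(norm):
        raise DegenerateReferenceError(f"{what}: reference shape is identically zero")
    peak = float(np.max(y))
    noise = noise_mad(y)
    if noise > 0 and peak < WEAK_REFERENCE_SNR * noise:
        raise WeakReferenceError(
            f"{what}: peak signal {peak:.3g} below {WEAK_REFERENCE_SNR}x noise MAD {noise:.3g}"
        )
    return y / norm, norm


@dataclass
class ChannelBasis:
    """Unmixing design matrix for one excitation channel."""

    excitation_nm: float
    grid: np.ndarray
    component_names: list[str]
    matrix: np.ndarray  # columns are unit-norm shapes, ordered as component_names

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass
class ReferenceBasis:
    """Component spectra of one experiment plus the acceptor crosstalk ratio.

    ``crosstalk_rho`` is the fitted acceptor amplitude of the acceptor-only
    reference under donor excitation divided by its fitted amplitude under
    acceptor excitation; it converts acceptor-channel acceptor amplitude into
    the directly excited acceptor contribution expected in the donor channel.
    """

    donor_channel: ChannelBasis
    acceptor_channel: ChannelBasis
    crosstalk_rho: float
    background_norms: dict[float, float] = field(default_factory=dict)

    def channel(self, excitation_nm: float) -> ChannelBasis:
        for ch in (self.donor_channel, self.acceptor_channel):
            if ch.excitation_nm == excitation_nm:
                return ch
        raise KeyError(f"no basis for excitation {excitation_nm:g} nm")


@dataclass
class UnmixResult:
    """Fitted component amplitudes and residual diagnostics for one scan."""

    sample_id: str
    excitation_nm: float
    amplitudes: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float
    residual_scale: float  # 1.4826 * MAD of residuals
    condition_number: float
    replicate: int = 1


def build_reference_basis(
    buffer_by_channel: dict[float, EmissionSpectrum],
    empty_by_channel: dict[float, EmissionSpectrum],
    donor_ref: EmissionSpectrum,
    acceptor_ref_by_channel: dict[float, EmissionSpectrum],
) -> ReferenceBasis:
    """Build the per-experiment basis from raw reference scans.

    All scans must already share the channel grids.  Buffer subtraction and
    empty-cell subtraction are applied here; shapes are unit-normalized
    (Euclidean norm 1 on their grid).
    """
    channels = sorted(buffer_by_channel)
    if len(channels) != 2:
        raise DegenerateReferenceError(f"need two excitation channels, got {channels}")
    donor_exc, acceptor_exc = channels

    empty_bs = {
        ch: subtract_buffer(empty_by_channel[ch], buffer_by_channel[ch]) for ch in channels
    }
    bg_shapes, bg_norms = {}, {}
    for ch in channels:
        bg_shapes[ch], bg_norms[ch] = _unit_shape(
            empty_bs[ch].intensities, f"empty_cell@{ch:g}"
        )

    def fluorophore_shape(ref: EmissionSpectrum, ch: float, what: str) -> np.ndarray:
        bs = subtract_buffer(ref, buffer_by_channel[ch])
        clean = subtract_background_reference(bs, empty_bs[ch])
        shape, _ = _unit_shape(clean.intensities, what)
        return shape

    donor_shape = fluorophore_shape(donor_ref, donor_exc, "donor_ref")
    acc_shape = {
        ch: fluorophore_shape(acceptor_ref_by_channel[ch], ch, f"acceptor_ref@{ch:g}")
        for ch in channels
    }

    donor_basis = ChannelBasis(
        excitation_nm=donor_exc,
        grid=buffer_by_channel[donor_exc].wavelengths,
        component_names=["background", "donor", "acceptor"],
        matrix=np.column_stack([bg_shapes[donor_exc], donor_shape, acc_shape[donor_exc]]),
    )
    acceptor_basis = ChannelBasis(
        excitation_nm=acceptor_exc,
        grid=buffer_by_channel[acceptor_exc].wavelengths,
        component_names=["background", "acceptor"],
        matrix=np.column_stack([bg_shapes[acceptor_exc], acc_shape[acceptor_exc]]),
    )
    basis = ReferenceBasis(
        donor_channel=donor_basis,
        acceptor_channel=acceptor_basis,
        crosstalk_rho=np.nan,
        background_norms=bg_norms,
    )

    # crosstalk ratio from the acceptor reference's fitted amplitudes
    amp = {}
    for ch, chan_basis in ((donor_exc, donor_basis), (acceptor_exc, acceptor_basis)):
        bs = subtract_buffer(acceptor_ref_by_channel[ch], buffer_by_channel[ch])
        res = unmix_spectrum(bs, basis, channel=ch)
        amp[ch] = res.amplitudes["acceptor"]
    if amp[acceptor_exc] <= 0 or amp[donor_exc] <= 0:
        raise DegenerateReferenceError(
            "acceptor reference has no fitted acceptor signal in one channel "
            f"(amplitudes {amp}); crosstalk ratio undefined"
        )
    rho = amp[donor_exc] / amp[acceptor_exc]
    if not np.isfinite(rho) or rho <= 0:
        raise DegenerateReferenceError(f"crosstalk ratio not finite/positive: {rho}")
    basis.crosstalk_rho = float(rho)
    return basis


def unmix_spectrum(
    s: EmissionSpectrum, basis: ReferenceBasis, channel: float | None = None
) -> UnmixResult:
    """Decompose a buffer-subtracted scan into nonnegative component amplitudes.

    Solves ``min || s - B a ||_2  s.t.  a >= 0`` where the columns of ``B``
    are the channel's unit-norm component shapes.
    """
    ch = basis.channel(channel if channel is not None else s.excitation_nm)
    if len(s) != ch.grid.size or not np.allclose(s.wavelengths, ch.grid):
        _raise_alignment(s, ch)
    if len(s) < ch.matrix.shape[1]:
        raise UnderdeterminedError(
            f"{s.sample_id}: {len(s)} points for {ch.matrix.shape[1]} components"
        )
    cond = ch.condition_number
    if cond > COND_FAIL:
        raise CollinearityError(
            f"basis condition number {cond:.3g} exceeds {COND_FAIL:g} "
            f"in the {ch.excitation_nm:g} nm channel"
        )
    if cond > COND_WARN:
        warnings.warn(
            f"basis condition number {cond:.3g} above {COND_WARN:g}", stacklevel=2
        )
    y = s.intensities
    coef, _ = nnls(ch.matrix, y)
    fitted = ch.matrix @ coef
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    scale = 1.4826 * float(np.median(np.abs(residuals - np.median(residuals))))
    return UnmixResult(
        sample_id=s.sample_id,
        excitation_nm=ch.excitation_nm,
        amplitudes=dict(zip(ch.component_names, (float(c) for c in coef))),
        fitted=fitted,
        residuals=residuals,
        r_squared=r_squared,
        residual_scale=scale,
        condition_number=cond,
        replicate=s.replicate,
    )


def _raise_alignment(s: EmissionSpectrum, ch: ChannelBasis):
    from .errors import AlignmentError

    raise AlignmentError(
        f"{s.sample_id}: scan grid does not match the {ch.excitation_nm:g} nm basis grid"
    )
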