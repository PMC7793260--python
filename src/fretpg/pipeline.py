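"""End-to-end analysis: manifest -> basis -> unmixing -> Ef_A -> statistics.

This is the glue the CLI (and the tests) drive; all science lives in
:mod:`fretpg.unmixing` and :mod:`fretpg.fret_quant`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ManifestError
from .fret_quant import (
    FretCalibration,
    FretResult,
    GroupComparison,
    ReplicateSummary,
    compare_groups,
    compute_efa,
    summarize_replicates,
)
from .spectra_io import (
    SAMPLE_ROLES,
    EmissionSpectrum,
    ExperimentManifest,
    load_entry,
    resample_to_grid,
)
from .unmixing import ReferenceBasis, UnmixResult, build_reference_basis, subtract_buffer, unmix_spectrum


@dataclass
class ExperimentResults:
    basis: ReferenceBasis
    unmix_results: list[UnmixResult]
    fret_results: list[FretResult]
    summaries: list[ReplicateSummary]
    comparisons: list[GroupComparison] = field(default_factory=list)

    def efa_by_group(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for r in self.fret_results:
            out.setdefault(r.sample_id, []).append(r.efa)
        return out

    def unmix_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.unmix_results:
            row = {
                "sample_id": u.sample_id,
                "excitation_nm": u.excitation_nm,
                "replicate": u.replicate,
                "r_squared": u.r_squared,
                "residual_mad": u.residual_scale,
            }
            for name, amp in u.amplitudes.items():
                row[f"amp_{name}"] = amp
            rows.append(row)
        return pd.DataFrame(rows)

    def fret_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "replicate": r.replicate,
                    "efa_pct": r.efa,
                    "sensitized": r.sensitized,
                    "direct_acceptor_541": r.direct_acceptor_541,
                    "acceptor_total_587": r.acceptor_total_587,
                    "donor_amplitude_541": r.donor_amplitude_541,
                    "qc_flags": ";".join(r.qc_flags),
                }
                for r in self.fret_results
            ]
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group": s.group, "efa_pct": s.mean_efa, "sd_pct": s.sd, "n": s.n}
                for s in self.summaries
            ]
        )

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "t": c.t_statistic,
                    "df": c.df,
                    "p_value": c.p_value,
                    "stars": c.stars,
                }
                for c in self.comparisons
            ]
        )


def analyze_spectra(
    spectra: list[EmissionSpectrum],
    cal: FretCalibration = FretCalibration(),
    compare: bool = True,
) -> ExperimentResults:
    """Run the full quantification on an in-memory set of scans.

    The set must contain, per excitation channel, one buffer and one
    empty-cell scan, a donor reference in the donor channel and acceptor
    references in both channels, plus paired sample scans.
    """
    channels = sorted({s.excitation_nm for s in spectra})
    if len(channels) != 2:
        raise ManifestError(f"expected two excitation channels, found {channels}")
    donor_ch, acceptor_ch = channels

    def one(role: str, ch: float) -> EmissionSpectrum:
        found = [s for s in spectra if s.role == role and s.excitation_nm == ch]
        if len(found) != 1:
            raise ManifestError(f"need exactly one {role} scan at {ch:g} nm, found {len(found)}")
        return found[0]

    buffer_by = {ch: one("buffer", ch) for ch in channels}
    empty_by = {ch: one("empty_cell", ch) for ch in channels}
    basis = build_reference_basis(
        buffer_by_channel=buffer_by,
        empty_by_channel=empty_by,
        donor_ref=one("donor_ref", donor_ch),
        acceptor_ref_by_channel={ch: one("acceptor_ref", ch) for ch in channels},
    )

    samples = [s for s in spectra if s.role in SAMPLE_ROLES]
    by_key: dict[tuple[str, int], dict[float, EmissionSpectrum]] = {}
    for s in samples:
        by_key.setdefault((s.sample_id, s.replicate), {})[s.excitation_nm] = s

    unmix_results: list[UnmixResult] = []
    fret_results: list[FretResult] = []
    for (sid, rep), per_ch in sorted(by_key.items()):
        if set(per_ch) != set(channels):
            raise ManifestError(
                f"sample {sid!r} replicate {rep} missing a channel: has {sorted(per_ch)}"
            )
        u = {}
        for ch in channels:
            bs = subtract_buffer(per_ch[ch], buffer_by[ch])
            u[ch] = unmix_spectrum(bs, basis)
            unmix_results.append(u[ch])
        fret_results.append(compute_efa(u[donor_ch], u[acceptor_ch], basis, cal))

    groups: dict[str, list[FretResult]] = {}
    for r in fret_results:
        groups.setdefault(r.sample_id, []).append(r)
    summaries = [summarize_replicates(rs, g) for g, rs in groups.items()]

    comparisons = []
    if compare:
        for ga, gb in combinations(sorted(groups), 2):
            a = [r.efa for r in groups[ga]]
            b = [r.efa for r in groups[gb]]
            if len(a) >= 2 and len(b) >= 2:
                comparisons.append(compare_groups(a, b, ga, gb))

    return ExperimentResults(
        basis=basis,
        unmix_results=unmix_results,
        fret_results=fret_results,
        summaries=summaries,
        comparisons=comparisons,
    )


def simulate_replicate_experiments(
    kind: str,
    n_experiments: int,
    master_seed: int,
    cfg_overrides: dict | None = None,
    cal: FretCalibration = FretCalibration(),
    via_disk: bool = False,
    workdir: str | Path | None = None,
) -> tuple[list[FretResult], pd.DataFrame]:
    """Simulate ``n_experiments`` independent biological repeats of one sample kind.

    Each repeat is a complete experiment with its own reference scans (buffer,
    empty cell, donor-only, acceptor-only) and a freshly built unmixing basis,
    mirroring how replicate efficiencies are accumulated across separately
    measured cultures.  Per-experiment seeds are spawned from ``master_seed``.
    With ``via_disk`` every experiment is round-tripped through the on-disk
    scan/manifest formats before analysis.

    Returns the per-repeat FRET results and the concatenated ground truth.
    """
    import tempfile

    from .synthetic import SyntheticPanelConfig, simulate_panel

    overrides = dict(cfg_overrides or {})
    overrides["n_replicates"] = 1
    results: list[FretResult] = []
    truths = []
    for i, child in enumerate(np.random.SeedSequence(master_seed).spawn(n_experiments)):
        seed = int(child.generate_state(1)[0] % 2**31)
        cfg = SyntheticPanelConfig.default(seed=seed, **overrides)
        panel = simulate_panel([(kind, {})], cfg)
        if via_disk:
            with tempfile.TemporaryDirectory(dir=workdir) as tmp:
                manifest_path = panel.write(tmp)
                from .spectra_io import load_manifest

                res = analyze_manifest(load_manifest(manifest_path), Path(tmp), cal)
        else:
            res = analyze_spectra(panel.spectra, cal, compare=False)
        (result,) = res.fret_results
        result = FretResult(**{**result.__dict__, "replicate": i + 1})
        results.append(result)
        truth = panel.ground_truth.copy()
        truth["replicate"] = i + 1
        truth["experiment_seed"] = seed
        truths.append(truth)
    return results, pd.concat(truths, ignore_index=True)


def analyze_manifest(
    manifest: ExperimentManifest,
    base_dir: str | Path = ".",
    cal: FretCalibration = FretCalibration(),
) -> ExperimentResults:
    """Load every scan listed in a manifest, align grids, and analyze."""
    manifest.validate()
    spectra = []
    for entry in manifest.entries:
        s = load_entry(entry, base_dir)
        grid = manifest.grids.get(entry.excitation_nm)
        if grid is not None:
            s = resample_to_grid(s, grid)
        spectra.append(s)
    return analyze_spectra(spectra, cal)
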