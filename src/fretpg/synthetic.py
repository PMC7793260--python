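"""Synthetic spectral panels and muropeptide tables with known ground truth.

The generator emulates the structure of a spectrofluorimeter FRET experiment:
two overlapping fluorophore emission bands (skew-normal shapes standing in
for mKO and mCherry), a broad cellular autofluorescence background, a flat
buffer baseline, direct excitation of the acceptor at the donor excitation
wavelength, sensitized emission proportional to (complexed fraction) x
(true transfer efficiency), and additive Gaussian measurement noise.

The photophysical model is chosen so that the analysis pipeline's Ef_A
estimator is exactly unbiased at zero noise: for a sample with donor
abundance D, acceptor abundance A, complexed fraction f and true efficiency
E, the donor-channel scan carries

    donor amplitude     x_D(541) * (D - E * f * min(D, A))      (donor quenching)
    acceptor amplitude  x_A(541) * A + sens
    sens                x_A(541) * E * f * min(D, A) / kappa

and the acceptor-channel scan carries ``x_A(587) * A``.  The analyzer's
crosstalk ratio then recovers the direct term exactly and
``Ef_A = 100 * E * f * min(D, A) / A`` (equal to ``100 * f * E`` for a
tandem construct, where one molecule carries both fluorophores and D = A).

Replicate-to-replicate biological variation is modelled as log-normal
scatter on abundances and background, emulating expression variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import skewnorm

from .errors import ConfigError, DomainError
from .spectra_io import (
    EmissionSpectrum,
    ExperimentManifest,
    ManifestEntry,
    make_grid,
    write_manifest,
    write_spectrum,
)

PANEL_KINDS = ("tandem", "negative", "pair")
_KIND_ROLE = {"tandem": "tandem", "negative": "negative", "pair": "fret_sample"}

#: decay constant (nm) of the model autofluorescence background
AUTOFLUORESCENCE_DECAY_NM = 60.0


def load_defaults() -> dict:
    """Packaged default geometry, fluorophore and simulation parameters."""
    with resources.files("fretpg").joinpath("data/defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class FluorophoreModel:
    """Skew-normal emission band plus per-channel excitation efficiencies."""

    name: str
    emission_peak_nm: float
    emission_width_nm: float
    emission_skew: float
    relative_excitation: dict[float, float]
    quantum_scale: float = 1.0

    def __post_init__(self):
        if self.emission_width_nm <= 0:
            raise DomainError(f"{self.name}: emission width must be > 0")
        if any(v < 0 for v in self.relative_excitation.values()):
            raise DomainError(f"{self.name}: excitation efficiencies must be >= 0")

    def excitation(self, channel_nm: float) -> float:
        return float(self.relative_excitation.get(channel_nm, 0.0))

    @classmethod
    def from_dict(cls, d: dict) -> "FluorophoreModel":
        rel = {float(k): float(v) for k, v in d["relative_excitation"].items()}
        return cls(
            name=d["name"],
            emission_peak_nm=float(d["emission_peak_nm"]),
            emission_width_nm=float(d["emission_width_nm"]),
            emission_skew=float(d.get("emission_skew", 0.0)),
            relative_excitation=rel,
            quantum_scale=float(d.get("quantum_scale", 1.0)),
        )


def _mode_offset(skew: float) -> float:
    """Standardized mode of a skew-normal, located numerically."""
    z = np.linspace(-4.0, 4.0, 8001)
    return float(z[np.argmax(skewnorm.pdf(z, skew))])


def emission_density(model: FluorophoreModel, grid: np.ndarray) -> np.ndarray:
    """Skew-normal emission density on the grid, mode anchored at the peak."""
    grid = np.asarray(grid, dtype=float)
    w, a = model.emission_width_nm, model.emission_skew
    loc = model.emission_peak_nm - w * _mode_offset(a)
    if grid[0] > model.emission_peak_nm - 3 * w or grid[-1] < model.emission_peak_nm + 3 * w:
        warnings.warn(
            f"{model.name}: grid [{grid[0]:g}, {grid[-1]:g}] truncates the emission band "
            f"(peak {model.emission_peak_nm:g} +/- 3x{w:g} nm)",
            stacklevel=2,
        )
    return skewnorm.pdf(grid, a, loc=loc, scale=w)


def emission_shape(model: FluorophoreModel, grid: np.ndarray) -> np.ndarray:
    """Unit-Euclidean-norm emission shape on the grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y = emission_density(model, grid)
    norm = float(np.linalg.norm(y))
    if norm <= 0 or not np.isfinite(norm):
        raise DomainError(f"{model.name}: emission band has no support on the grid")
    return y / norm


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Ground-truth photophysical parameters driving the generator."""

    donor: FluorophoreModel
    acceptor: FluorophoreModel
    donor_excitation_nm: float = 541.0
    acceptor_excitation_nm: float = 587.0
    windows: dict[float, tuple[float, float, float]] = field(default_factory=dict)
    donor_abundance: float = 1000.0
    acceptor_abundance: float = 1000.0
    complex_fraction: float = 1.0
    true_efficiency: float = 0.31
    kappa: float = 1.0
    background_scale: float = 200.0
    buffer_level: float = 20.0
    noise_sigma: float = 0.01
    replicate_cv: float = 0.10
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.complex_fraction <= 1.0:
            raise ConfigError(f"complex_fraction must be in [0, 1]: {self.complex_fraction}")
        if not 0.0 <= self.true_efficiency < 1.0:
            raise ConfigError(f"true_efficiency must be in [0, 1): {self.true_efficiency}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.donor_abundance <= 0 or self.acceptor_abundance <= 0:
            raise ConfigError("abundances must be > 0")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    @classmethod
    def default(cls, **overrides) -> "SyntheticPanelConfig":
        d = load_defaults()
        sim = d["simulation"]
        ch = d["channels"]
        windows = {
            float(k): tuple(float(x) for x in v) for k, v in d["windows"].items()
        }
        base = dict(
            donor=FluorophoreModel.from_dict(d["fluorophores"]["donor"]),
            acceptor=FluorophoreModel.from_dict(d["fluorophores"]["acceptor"]),
            donor_excitation_nm=float(ch["donor_excitation_nm"]),
            acceptor_excitation_nm=float(ch["acceptor_excitation_nm"]),
            windows=windows,
            donor_abundance=float(sim["donor_abundance"]),
            acceptor_abundance=float(sim["acceptor_abundance"]),
            background_scale=float(sim["background_scale"]),
            buffer_level=float(sim["buffer_level"]),
            noise_sigma=float(sim["noise_sigma"]),
            replicate_cv=float(sim["replicate_cv"]),
            kappa=float(d["calibration"]["kappa"]),
        )
        base.update(overrides)
        return cls(**base)

    @property
    def channels(self) -> tuple[float, float]:
        return (self.donor_excitation_nm, self.acceptor_excitation_nm)

    def grid(self, channel: float) -> np.ndarray:
        return make_grid(*self.windows[channel])


@dataclass
class SyntheticPanel:
    """In-memory synthetic experiment: all scans plus the ground-truth table."""

    spectra: list[EmissionSpectrum]
    ground_truth: pd.DataFrame
    config: SyntheticPanelConfig
    seed: int

    def write(self, outdir: str | Path) -> Path:
        """Write all scans, the manifest and the ground-truth table; return the manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = []
        for s in self.spectra:
            fname = f"{s.sample_id}_{s.excitation_nm:g}nm_rep{s.replicate}.csv"
            write_spectrum(s, outdir / fname)
            entries.append(
                ManifestEntry(
                    path=fname,
                    sample_id=s.sample_id,
                    role=s.role,
                    excitation_nm=s.excitation_nm,
                    replicate=s.replicate,
                )
            )
        grids = {ch: self.config.windows[ch] for ch in self.config.channels}
        manifest = ExperimentManifest(entries=entries, grids=grids)
        manifest.validate()
        manifest_path = outdir / "manifest.csv"
        write_manifest(manifest, manifest_path)
        gt = self.ground_truth.copy()
        gt["seed"] = self.seed
        gt.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        return manifest_path


class _PanelBuilder:
    def __init__(self, cfg: SyntheticPanelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.grids = {ch: cfg.grid(ch) for ch in cfg.channels}
        self.af = {}
        for ch, g in self.grids.items():
            raw = np.exp(-(g - g[0]) / AUTOFLUORESCENCE_DECAY_NM)
            self.af[ch] = raw / np.linalg.norm(raw)
        self.donor_shape = {ch: emission_shape(cfg.donor, g) for ch, g in self.grids.items()}
        self.acceptor_shape = {
            ch: emission_shape(cfg.acceptor, g) for ch, g in self.grids.items()
        }

    def scatter(self) -> float:
        cv = self.cfg.replicate_cv
        if cv <= 0:
            return 1.0
        sigma = np.sqrt(np.log1p(cv**2))
        return float(np.exp(self.rng.normal(0.0, sigma)))

    def scan(
        self,
        channel: float,
        sample_id: str,
        role: str,
        replicate: int = 1,
        bg_amp: float = 0.0,
        donor_amp: float = 0.0,
        acceptor_amp: float = 0.0,
    ) -> EmissionSpectrum:
        cfg = self.cfg
        g = self.grids[channel]
        y = (
            cfg.buffer_level
            + bg_amp * self.af[channel]
            + donor_amp * self.donor_shape[channel]
            + acceptor_amp * self.acceptor_shape[channel]
        )
        if cfg.noise_sigma > 0:
            peak = float(np.max(y))
            y = y + self.rng.normal(0.0, cfg.noise_sigma * peak, size=g.size)
        return EmissionSpectrum(
            sample_id=sample_id,
            excitation_nm=channel,
            wavelengths=g,
            intensities=y,
            role=role,
            replicate=replicate,
        )

    def references(self) -> list[EmissionSpectrum]:
        cfg = self.cfg
        out = []
        for ch in cfg.channels:
            out.append(self.scan(ch, "buffer", "buffer"))
            out.append(self.scan(ch, "empty_cell", "empty_cell", bg_amp=cfg.background_scale))
        dch = cfg.donor_excitation_nm
        out.append(
            self.scan(
                dch,
                "donor_ref",
                "donor_ref",
                bg_amp=cfg.background_scale,
                donor_amp=cfg.donor.excitation(dch) * cfg.donor_abundance,
            )
        )
        for ch in cfg.channels:
            out.append(
                self.scan(
                    ch,
                    "acceptor_ref",
                    "acceptor_ref",
                    bg_amp=cfg.background_scale,
                    acceptor_amp=cfg.acceptor.excitation(ch) * cfg.acceptor_abundance,
                )
            )
        return out

    def sample(self, kind: str, sample_id: str, replicate: int):
        cfg = self.cfg
        if kind not in PANEL_KINDS:
            raise ConfigError(f"unknown sample kind {kind!r}; expected one of {PANEL_KINDS}")
        if kind == "tandem":
            shared = cfg.donor_abundance * self.scatter()
            d_ab = a_ab = shared
            f, e = 1.0, cfg.true_efficiency
        else:
            d_ab = cfg.donor_abundance * self.scatter()
            a_ab = cfg.acceptor_abundance * self.scatter()
            f = 0.0 if kind == "negative" else cfg.complex_fraction
            e = cfg.true_efficiency
        bg = cfg.background_scale * self.scatter()
        dch, ach = cfg.channels
        x_d, x_a = cfg.donor.excitation, cfg.acceptor.excitation
        complexed = f * min(d_ab, a_ab)
        sens = x_a(dch) * e * complexed / cfg.kappa
        s541 = self.scan(
            dch,
            sample_id,
            _KIND_ROLE[kind],
            replicate,
            bg_amp=bg,
            donor_amp=x_d(dch) * (d_ab - e * complexed),
            acceptor_amp=x_a(dch) * a_ab + sens,
        )
        s587 = self.scan(
            ach,
            sample_id,
            _KIND_ROLE[kind],
            replicate,
            bg_amp=bg,
            donor_amp=x_d(ach) * d_ab,
            acceptor_amp=x_a(ach) * a_ab,
        )
        direct = x_a(dch) * a_ab
        truth = {
            "sample_id": sample_id,
            "replicate": replicate,
            "kind": kind,
            "complex_fraction": f,
            "true_efficiency": e,
            "donor_abundance": d_ab,
            "acceptor_abundance": a_ab,
            "efa_true_pct": 100.0 * cfg.kappa * sens / direct if direct > 0 else np.nan,
        }
        return [s541, s587], truth


def simulate_pair_spectra(
    cfg: SyntheticPanelConfig, kind: str = "pair", sample_id: str | None = None
) -> SyntheticPanel:
    """Simulate one sample group (with shared references) under ``cfg``.

    Deterministic for a fixed config and seed.
    """
    return simulate_panel([(kind, {})], cfg, sample_ids=[sample_id or kind])


def simulate_panel(
    design: list[tuple[str, dict]],
    cfg: SyntheticPanelConfig | None = None,
    sample_ids: list[str] | None = None,
) -> SyntheticPanel:
    """Simulate a full experiment: shared references plus one sample group per
    design entry ``(kind, config overrides)``."""
    if not design:
        raise ConfigError("panel design is empty")
    cfg = cfg or SyntheticPanelConfig.default()
    ids = sample_ids or [ov.get("sample_id", kind) for kind, ov in design]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate sample ids in design: {ids}")
    rng = np.random.default_rng(cfg.seed)
    builder = _PanelBuilder(cfg, rng)
    spectra = builder.references()
    truths = []
    for (kind, overrides), sid in zip(design, ids):
        overrides = {k: v for k, v in overrides.items() if k != "sample_id"}
        sub_cfg = replace(cfg, **overrides) if overrides else cfg
        sub = _PanelBuilder.__new__(_PanelBuilder)
        sub.__dict__.update(builder.__dict__)
        sub.cfg = sub_cfg
        for rep in range(1, sub_cfg.n_replicates + 1):
            scans, truth = sub.sample(kind, sid, rep)
            spectra.extend(scans)
            truths.append(truth)
    return SyntheticPanel(
        spectra=spectra,
        ground_truth=pd.DataFrame(truths),
        config=cfg,
        seed=cfg.seed,
    )


# -- muropeptide table generator -------------------------------------------

#: proportions used to spread the monomer total over plausible species rows
_MONOMER_SPLIT = {
    ("Di", 2, "none"): 0.027,
    ("Tri", 3, "none"): 0.095,
    ("Tetra", 4, "none"): 0.791,
    ("TetraAnh", 4, "anhydro"): 0.017,
    ("TetraLysArg", 4, "lys_arg"): 0.070,
}
_DIMER_SPLIT = {("TetraTri", 3, "none"): 0.08, ("TetraTetra", 4, "none"): 0.92}


def simulate_muro_table(
    target_chain_length_ds: float,
    target_crosslinkage_pct: float,
    noise: float = 0.0,
    seed: int | None = None,
    trimer_to_dimer_ratio: float = 0.109,
    sample: str = "synthetic",
) -> pd.DataFrame:
    """Construct a peak table whose derived metrics hit the given targets.

    Inverts the derived-row formulas: chain ends = 100 / chain length;
    dimer/trimer totals solve ``dimers/2 + 2/3 * trimers = X`` with a fixed
    trimer:dimer ratio.  With ``noise = 0`` the analyzer recovers the targets
    exactly; multiplicative log-normal noise (SD = ``noise``) otherwise.
    """
    if target_chain_length_ds < 2:
        raise ConfigError("chain length must be >= 2 disaccharide units")
    if not 0.0 <= target_crosslinkage_pct < 60.0:
        raise ConfigError("cross-linkage must be in [0, 60)%")
    x = target_crosslinkage_pct
    dimers = x / (0.5 + (2.0 / 3.0) * trimer_to_dimer_ratio)
    trimers = trimer_to_dimer_ratio * dimers
    monomers = 100.0 - dimers - trimers
    if monomers < 0:
        raise ConfigError(
            f"infeasible targets: oligomer totals {dimers + trimers:.1f}% exceed 100%"
        )
    chain_ends = 100.0 / target_chain_length_ds
    rng = np.random.default_rng(seed)

    def jitter(v: float) -> float:
        if noise <= 0:
            return v
        sigma = np.sqrt(np.log1p(noise**2))
        return v * float(np.exp(rng.normal(0.0, sigma)))

    rows = []
    for (name, length, mod), frac in _MONOMER_SPLIT.items():
        rows.append((name, "monomer", "species", length, mod, jitter(monomers * frac)))
    rows.append(("Dimers_total", "dimer", "total", None, "none", jitter(dimers)))
    for (name, length, mod), frac in _DIMER_SPLIT.items():
        rows.append((name, "dimer", "species", length, mod, jitter(dimers * frac)))
    rows.append(("Trimers_total", "trimer", "total", None, "none", jitter(trimers)))
    rows.append(("ChainEndsAnh", "chain_ends", "chain_ends", None, "anhydro", jitter(chain_ends)))
    return pd.DataFrame(
        rows,
        columns=["species", "oligomer_class", "row_type", "peptide_length", "modification", sample],
    )
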