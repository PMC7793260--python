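"""Peptidoglycan composition metrics from HPLC muropeptide peak-area tables.

Input is a delimited table of muropeptide species (Glauner nomenclature) with
their oligomer class (monomer / dimer / trimer / ...), optional peptide
length and modification annotations, and one percent-peak-area column per
sample.  Real published tables are often partial: a class total row may be
printed even though not every minor species is listed, and modification
sub-rows (anhydro, Lys-Arg) may either partition the class or overlap with
the peptide-length rows.  Both behaviours are table-layout options here, not
hard-coded assumptions.

Derived metrics:

* degree of cross-linkage: each n-mer contributes (n-1)/n of its area,
  i.e. dimers/2 + 2/3 * trimers + ...;
* mean glycan chain length in disaccharide (DS) units: 100 divided by the
  percentage of anhydro-MurNAc chain ends;
* percent of peptides in cross-links: reported as the plain oligomer area
  fraction (dimers + trimers + ...), with an explicit provenance note --
  published tables use a weighting that is not recoverable from the printed
  rows, so this estimate can differ from printed values by a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ClassificationError, DomainError

OLIGOMER_ORDER = {"monomer": 1, "dimer": 2, "trimer": 3, "tetramer": 4}

#: Default table-layout flags: do the anhydro/Lys-Arg sub-rows of a class
#: overlap with its peptide-length rows (True) or partition the class (False)?
DEFAULT_OVERLAPPING_MODIFICATIONS: Mapping[str, bool] = {
    "monomer": False,
    "dimer": True,
    "trimer": True,
    "tetramer": True,
}

_META_COLUMNS = ["species", "oligomer_class", "row_type", "peptide_length", "modification"]


def reference_table_path() -> Path:
    """Packaged muropeptide table of E. coli LMC500 strains (percent peak areas)."""
    return Path(resources.files("fretpg").joinpath("data/ecoli_lmc500_muropeptides.tsv"))


def load_peak_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a muropeptide peak table (TSV/CSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"species": str})
    return validate_peak_table(df)


def validate_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ClassificationError(f"peak table missing columns {missing}")
    df = df.copy()
    df["row_type"] = df["row_type"].fillna("species")
    df["modification"] = df["modification"].fillna("none")
    bad = set(df["oligomer_class"]) - set(OLIGOMER_ORDER) - {"chain_ends"}
    if bad:
        rows = df[df["oligomer_class"].isin(bad)]["species"].tolist()
        raise ClassificationError(f"unknown oligomer class(es) {sorted(bad)} in rows {rows}")
    samples = sample_columns(df)
    if not samples:
        raise ClassificationError("peak table has no sample columns")
    if (df[samples] < 0).any().any():
        raise DomainError("negative percent areas in peak table")
    return df


def sample_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in _META_COLUMNS]


@dataclass
class ClassTotals:
    """Per-class percent-area totals and sub-class breakdowns for one sample."""

    sample: str
    totals: dict[str, float]
    by_length: dict[int, float]
    anhydro: dict[str, float]
    lys_arg: dict[str, float]
    chain_ends_anhydro: float | None
    unassigned: float
    warnings: list[str] = field(default_factory=list)


def aggregate_classes(
    df: pd.DataFrame,
    sample: str,
    overlapping_modifications: Mapping[str, bool] = DEFAULT_OVERLAPPING_MODIFICATIONS,
) -> ClassTotals:
    """Sum percent areas by oligomer class and sub-class.

    An explicit ``row_type == "total"`` row for a class takes precedence over
    summing its species rows (printed tables often omit minor species from the
    listed rows while the total covers everything).  Otherwise the class total
    is the sum of its species rows; modification rows are included in the sum
    only when the layout flags declare them disjoint from the length rows.
    """
    df = validate_peak_table(df)
    if sample not in df.columns:
        raise ClassificationError(f"sample column {sample!r} not in table")
    totals: dict[str, float] = {}
    anhydro: dict[str, float] = {}
    lys_arg: dict[str, float] = {}
    warnings: list[str] = []
    for cls in OLIGOMER_ORDER:
        rows = df[df["oligomer_class"] == cls]
        if rows.empty:
            continue
        explicit = rows[rows["row_type"] == "total"]
        species = rows[rows["row_type"] == "species"]
        anhydro[cls] = float(species.loc[species["modification"] == "anhydro", sample].sum())
        lys_arg[cls] = float(species.loc[species["modification"] == "lys_arg", sample].sum())
        if not explicit.empty:
            totals[cls] = float(explicit[sample].sum())
        else:
            overlap = overlapping_modifications.get(cls, True)
            counted = species if not overlap else species[species["modification"] == "none"]
            totals[cls] = float(counted[sample].sum())
    lengths = df[(df["row_type"] == "species") & df["peptide_length"].notna()]
    by_length = {
        int(length): float(grp[sample].sum())
        for length, grp in lengths.groupby("peptide_length")
    }
    ce_rows = df[df["oligomer_class"] == "chain_ends"]
    chain_ends = float(ce_rows[sample].sum()) if not ce_rows.empty else None
    grand = sum(totals.values())
    unassigned = 100.0 - grand
    if not 95.0 <= grand <= 105.0:
        warnings.append(f"class totals sum to {grand:.1f}% (outside [95, 105])")
    return ClassTotals(
        sample=sample,
        totals=totals,
        by_length=by_length,
        anhydro=anhydro,
        lys_arg=lys_arg,
        chain_ends_anhydro=chain_ends,
        unassigned=unassigned,
        warnings=warnings,
    )


def _as_totals(totals: "ClassTotals | Mapping[str, float]") -> Mapping[str, float]:
    return totals.totals if isinstance(totals, ClassTotals) else totals


def degree_of_crosslinkage(totals: "ClassTotals | Mapping[str, float]") -> float:
    """Percent of peptides cross-linked: sum over n-mers of (n-1)/n * area%."""
    t = _as_totals(totals)
    out = 0.0
    for cls, pct in t.items():
        if cls not in OLIGOMER_ORDER:
            raise ClassificationError(f"unknown oligomer class {cls!r}")
        if pct < 0:
            raise DomainError(f"negative class total for {cls}: {pct}")
        n = OLIGOMER_ORDER[cls]
        out += pct * (n - 1) / n
    return out


def mean_chain_length(chain_ends_anhydro_pct: float) -> float:
    """Mean glycan chain length in disaccharide units: 100 / chain-ends%."""
    x = float(chain_ends_anhydro_pct)
    if x <= 0:
        raise DomainError(f"chain-end percentage must be > 0, got {x}")
    return 100.0 / x


@dataclass(frozen=True)
class CrosslinkEstimate:
    value: float  # percent
    method: str
    note: str


def peptides_in_crosslinks(totals: "ClassTotals | Mapping[str, float]") -> CrosslinkEstimate:
    """Percent of peptides residing in cross-linked muropeptides.

    Implemented as the plain oligomer area fraction (dimers + trimers + ...).
    Published tables apply an additional weighting (per Glauner's scheme) that
    is not derivable from the printed class totals, so this value is reported
    with a provenance note rather than silently matching printed numbers.
    """
    t = _as_totals(totals)
    value = sum(pct for cls, pct in t.items() if OLIGOMER_ORDER.get(cls, 1) > 1)
    return CrosslinkEstimate(
        value=float(value),
        method="oligomer_area_fraction",
        note=(
            "plain dimer+trimer(+higher) area fraction; printed tables may use a "
            "peptide-count weighting and report a few percent higher"
        ),
    )


@dataclass
class CompositionSummary:
    """Derived composition metrics for one sample column."""

    sample: str
    monomers_total: float
    dimers_total: float
    trimers_total: float
    by_length: dict[int, float]
    anhydro_by_class: dict[str, float]
    lys_arg_by_class: dict[str, float]
    chain_ends_anhydro: float | None
    mean_chain_length_ds: float | None
    degree_crosslinkage: float
    peptides_in_crosslinks: CrosslinkEstimate
    unassigned: float
    warnings: list[str]


def summarize_composition(
    df: pd.DataFrame,
    sample: str,
    overlapping_modifications: Mapping[str, bool] = DEFAULT_OVERLAPPING_MODIFICATIONS,
) -> CompositionSummary:
    """Full composition summary (class totals plus derived metrics) for one sample."""
    agg = aggregate_classes(df, sample, overlapping_modifications)
    chain_ends = agg.chain_ends_anhydro
    if chain_ends is None:
        # fall back to the sum of anhydro-annotated species rows
        total_anh = sum(agg.anhydro.values())
        chain_ends = total_anh if total_anh > 0 else None
    return CompositionSummary(
        sample=sample,
        monomers_total=agg.totals.get("monomer", 0.0),
        dimers_total=agg.totals.get("dimer", 0.0),
        trimers_total=agg.totals.get("trimer", 0.0),
        by_length=agg.by_length,
        anhydro_by_class=agg.anhydro,
        lys_arg_by_class=agg.lys_arg,
        chain_ends_anhydro=chain_ends,
        mean_chain_length_ds=mean_chain_length(chain_ends) if chain_ends else None,
        degree_crosslinkage=degree_of_crosslinkage(agg),
        peptides_in_crosslinks=peptides_in_crosslinks(agg),
        unassigned=agg.unassigned,
        warnings=agg.warnings,
    )


def summary_frame(df: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Composition summaries for several sample columns as one DataFrame."""
    samples = samples or sample_columns(df)
    rows = []
    for sample in samples:
        s = summarize_composition(df, sample)
        rows.append(
            {
                "sample": sample,
                "monomers_total_pct": s.monomers_total,
                "dimers_total_pct": s.dimers_total,
                "trimers_total_pct": s.trimers_total,
                "chain_ends_anhydro_pct": s.chain_ends_anhydro,
                "mean_chain_length_ds": s.mean_chain_length_ds,
                "degree_crosslinkage_pct": s.degree_crosslinkage,
                "peptides_in_crosslinks_pct": s.peptides_in_crosslinks.value,
                "unassigned_pct": s.unassigned,
            }
        )
    return pd.DataFrame(rows)
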