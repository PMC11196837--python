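"""Lineage reference-allele-frequency panels and colony SNP observations.

A :class:`LineagePanel` holds, for each ancestry-informative SNP, the
reference-allele frequency in each source lineage (African *A*, Western
European *M*, Eastern European *C*).  A :class:`ColonyObservation` holds the
pooled reference-allele copy numbers observed for one colony (by default 40
allele copies = 2 x 20 pooled workers) aligned to a panel, plus the colony
metadata used downstream for grouping (apiary, beekeeping region, management,
coordinates).

Loci are biallelic and abstract: frequencies refer to a single designated
reference allele per SNP, the alternate allele's frequency being ``1 - p``.
Allele orientation is a property of the supplied panel file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_LINEAGES: tuple[str, ...] = ("A", "M", "C")
MANAGEMENT_LABELS = frozenset({"managed", "feral"})
MATERNAL_LINEAGES = frozenset({"A", "M", "C", "O", "Y", "unknown"})

PANEL_COLUMNS = ("snp_id", "freq_A", "freq_M", "freq_C")
COLONY_META_COLUMNS = (
    "colony_id",
    "apiary_id",
    "region",
    "management",
    "latitude",
    "longitude",
    "altitude",
    "n_alleles",
)


class PanelError(ValueError):
    """Malformed panel or colony input."""


@dataclass
class LineagePanel:
    """Per-SNP reference-allele frequencies for each source lineage.

    Parameters
    ----------
    snp_ids
        Ordered, unique locus identifiers (length L).
    freqs
        Array of shape ``(n_lineages, L)``; ``freqs[i, j]`` is the
        reference-allele frequency of lineage ``lineages[i]`` at SNP ``j``.
    lineages
        Ordered lineage labels; ``("A", "M", "C")`` by default.
    """

    snp_ids: list[str]
    freqs: np.ndarray
    lineages: tuple[str, ...] = DEFAULT_LINEAGES

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.lineages), len(self.snp_ids)):
            raise PanelError(
                f"freqs shape {self.freqs.shape} does not match "
                f"{len(self.lineages)} lineages x {len(self.snp_ids)} SNPs"
            )
        seen: set[str] = set()
        for s in self.snp_ids:
            if s in seen:
                raise PanelError(f"duplicate SNP id {s!r}")
            seen.add(s)
        bad = np.where((self.freqs < 0.0) | (self.freqs > 1.0))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise PanelError(
                f"frequency {self.freqs[i, j]} outside [0, 1] at SNP "
                f"{self.snp_ids[j]!r} (lineage {self.lineages[i]})"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.snp_ids)}

    def per_snp_divergence(self) -> np.ndarray:
        """Max pairwise |frequency difference| among lineages, per SNP."""
        return self.freqs.max(axis=0) - self.freqs.min(axis=0)

    def informativeness(self) -> float:
        """Mean over SNPs of the per-SNP divergence; 0 means useless panel."""
        return float(self.per_snp_divergence().mean())

    def permute_lineages(self, order: Sequence[str]) -> "LineagePanel":
        """Return a panel with lineage rows reordered to ``order``."""
        idx = [self.lineages.index(l) for l in order]
        return LineagePanel(list(self.snp_ids), self.freqs[idx], tuple(order))


@dataclass
class ColonyObservation:
    """Pooled per-SNP reference-allele counts for one colony plus metadata."""

    colony_id: str
    counts: np.ndarray  # int, aligned to a panel's snp_ids
    n_alleles: int = 40
    missing: np.ndarray | None = None  # bool mask, True where SNP unobserved
    apiary_id: str = ""
    region: str = ""
    management: str = "managed"
    latitude: float = float("nan")
    longitude: float = float("nan")
    altitude: float = float("nan")
    maternal_lineage: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.missing is None:
            self.missing = np.zeros(self.counts.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.counts.shape:
            raise PanelError("missing mask shape does not match counts")
        if self.n_alleles < 1:
            raise PanelError(f"n_alleles must be positive, got {self.n_alleles}")
        obs = self.counts[~self.missing]
        if obs.size == 0:
            raise PanelError(f"colony {self.colony_id!r} has no non-missing SNP")
        if obs.min() < 0 or obs.max() > self.n_alleles:
            j = int(np.where(~self.missing & ((self.counts < 0) | (self.counts > self.n_alleles)))[0][0])
            raise PanelError(
                f"colony {self.colony_id!r}: count {self.counts[j]} at SNP index {j} "
                f"outside [0, {self.n_alleles}]"
            )
        if self.management not in MANAGEMENT_LABELS:
            raise PanelError(
                f"colony {self.colony_id!r}: unknown management label "
                f"{self.management!r} (expected one of {sorted(MANAGEMENT_LABELS)})"
            )
        if self.maternal_lineage is not None and self.maternal_lineage not in MATERNAL_LINEAGES:
            raise PanelError(
                f"colony {self.colony_id!r}: unknown maternal lineage {self.maternal_lineage!r}"
            )

    @property
    def frequencies(self) -> np.ndarray:
        """Observed reference-allele frequencies p-hat = r / n_alleles."""
        return self.counts / float(self.n_alleles)


def freq_to_count(p_hat: float, n_alleles: int) -> int:
    """Convert an observed frequency to a copy number.

    Rounds ``p_hat * n_alleles`` half away from zero to the nearest integer
    and clips into ``[0, n_alleles]``.
    """
    x = p_hat * n_alleles
    r = math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)
    return int(min(max(r, 0), n_alleles))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read comma- or tab-delimited text, auto-detected from the header line."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"snp_id": str, "colony_id": str, "apiary_id": str})


def load_panel(
    path: str | Path,
    lineage_columns: Sequence[str] = ("freq_A", "freq_M", "freq_C"),
) -> LineagePanel:
    """Load a lineage reference panel from delimited text.

    The file must have a ``snp_id`` column and one frequency column per
    lineage; lineage labels are taken from the column names by stripping a
    ``freq_`` prefix.
    """
    df = _read_delimited(path)
    if "snp_id" not in df.columns:
        raise PanelError(f"{path}: missing required column 'snp_id'")
    for col in lineage_columns:
        if col not in df.columns:
            raise PanelError(f"{path}: missing lineage column {col!r}")
    snp_ids = df["snp_id"].astype(str).tolist()
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise PanelError(f"{path}: duplicated SNP id {dup.iloc[0]!r}")
    freqs = np.empty((len(lineage_columns), len(snp_ids)))
    for i, col in enumerate(lineage_columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise PanelError(
                f"{path}: non-numeric frequency in column {col!r} at SNP "
                f"{snp_ids[row]!r}"
            )
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            row = int(vals.index[bad][0])
            raise PanelError(
                f"{path}: frequency {vals.iloc[row]} outside [0, 1] at SNP "
                f"{snp_ids[row]!r} (column {col})"
            )
        freqs[i] = vals.to_numpy()
    lineages = tuple(c[5:] if c.startswith("freq_") else c for c in lineage_columns)
    return LineagePanel(snp_ids, freqs, lineages)


def write_panel(panel: LineagePanel, path: str | Path, sep: str = ",") -> None:
    """Write a panel to delimited text (inverse of :func:`load_panel`)."""
    df = pd.DataFrame({"snp_id": panel.snp_ids})
    for i, lin in enumerate(panel.lineages):
        df[f"freq_{lin}"] = panel.freqs[i]
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def load_colonies(
    path: str | Path,
    panel: LineagePanel,
    values: str = "auto",
) -> list[ColonyObservation]:
    """Load colony observations from delimited text, aligned to ``panel``.

    The file has the metadata columns (see :data:`COLONY_META_COLUMNS`) plus
    one column per SNP id holding either integer counts or frequencies.
    ``values`` selects the interpretation: ``"counts"``, ``"frequencies"``, or
    ``"auto"`` (counts when every non-missing SNP value is integral).
    Frequencies are converted to counts once at load time by
    :func:`freq_to_count`.  Panel SNPs absent from the file are marked
    missing; the file must share at least one SNP with the panel.
    """
    if values not in ("auto", "counts", "frequencies"):
        raise PanelError(f"values must be auto|counts|frequencies, got {values!r}")
    df = _read_delimited(path)
    for col in ("colony_id", "n_alleles"):
        if col not in df.columns:
            raise PanelError(f"{path}: missing required column {col!r}")
    snp_cols = [s for s in panel.snp_ids if s in df.columns]
    if not snp_cols:
        raise PanelError(f"{path}: no SNP columns overlap the panel")

    snp_data = df[snp_cols].apply(pd.to_numeric, errors="coerce")
    if values == "auto":
        finite = snp_data.to_numpy()[np.isfinite(snp_data.to_numpy())]
        is_counts = bool(finite.size) and np.allclose(finite, np.round(finite))
    else:
        is_counts = values == "counts"

    col_pos = {s: j for j, s in enumerate(panel.snp_ids)}
    out: list[ColonyObservation] = []
    for _, row in df.iterrows():
        n_alleles = int(row["n_alleles"])
        counts = np.zeros(panel.n_snps, dtype=int)
        missing = np.ones(panel.n_snps, dtype=bool)
        for s in snp_cols:
            v = pd.to_numeric(row[s], errors="coerce")
            if pd.isna(v):
                continue
            j = col_pos[s]
            if is_counts:
                r = int(round(float(v)))
                if not 0 <= r <= n_alleles:
                    raise PanelError(
                        f"{path}: colony {row['colony_id']!r} count {r} at SNP "
                        f"{s!r} outside [0, {n_alleles}]"
                    )
            else:
                if not 0.0 <= float(v) <= 1.0:
                    raise PanelError(
                        f"{path}: colony {row['colony_id']!r} frequency {v} at "
                        f"SNP {s!r} outside [0, 1]"
                    )
                r = freq_to_count(float(v), n_alleles)
            counts[j] = r
            missing[j] = False
        maternal = row.get("maternal_lineage")
        if maternal is not None and (pd.isna(maternal) or maternal == ""):
            maternal = None
        out.append(
            ColonyObservation(
                colony_id=str(row["colony_id"]),
                counts=counts,
                n_alleles=n_alleles,
                missing=missing,
                apiary_id=str(row.get("apiary_id", "")),
                region=str(row.get("region", "")),
                management=str(row.get("management", "managed")),
                latitude=float(row.get("latitude", float("nan"))),
                longitude=float(row.get("longitude", float("nan"))),
                altitude=float(row.get("altitude", float("nan"))),
                maternal_lineage=None if maternal is None else str(maternal),
            )
        )
    return out


def write_colonies(
    colonies: Sequence[ColonyObservation],
    panel: LineagePanel,
    path: str | Path,
    sep: str = ",",
) -> None:
    """Write colony observations as counts in the :func:`load_colonies` layout."""
    rows = []
    for c in colonies:
        row: dict[str, object] = {
            "colony_id": c.colony_id,
            "apiary_id": c.apiary_id,
            "region": c.region,
            "management": c.management,
            "latitude": c.latitude,
            "longitude": c.longitude,
            "altitude": c.altitude,
            "n_alleles": c.n_alleles,
            "maternal_lineage": c.maternal_lineage or "",
        }
        for j, s in enumerate(panel.snp_ids):
            row[s] = "" if c.missing[j] else int(c.counts[j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass
class InformativenessReport:
    per_snp: pd.DataFrame = field(repr=False)
    mean_divergence: float = 0.0
    uninformative_snps: list[str] = field(default_factory=list)


def panel_informativeness(panel: LineagePanel) -> InformativenessReport:
    """Per-SNP and mean lineage divergence; flags zero-divergence SNPs.

    Divergence at a SNP is the maximum pairwise absolute frequency difference
    among the lineages; a SNP where all lineages share one frequency carries
    no ancestry information and is flagged.
    """
    div = panel.per_snp_divergence()
    df = pd.DataFrame({"snp_id": panel.snp_ids, "divergence": div})
    flagged = [s for s, d in zip(panel.snp_ids, div) if d == 0.0]
    return InformativenessReport(
        per_snp=df,
        mean_divergence=float(div.mean()),
        uninformative_snps=flagged,
    )
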