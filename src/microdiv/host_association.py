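"""Host-association classification of OTUs from incidence tables.

Each sample carries a habitat label; samples labeled "Free-living"
(configurable, matched case-insensitively after trimming) were not
taken from a host, and every other label counts as host-derived.  An
OTU's occurrences are the samples it is present in (presence/absence,
never read-abundance weighted), split into host and free-living
occurrences:

* obligate host-associated — occurs only in host samples;
* preferentially host-associated — strictly more than half of its
  occurrences are in host samples;
* host-associated (any) — at least one host occurrence;

and symmetrically for free-living.  Exactly-50% ties belong to neither
preferential category.  The obligate host-associated and any-host
proportions bracket the fraction of taxa plausibly vulnerable to
host mass extinction (the mass-extinction model's q).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "OtuFlags",
    "HostAssociationSummary",
    "classify_otu",
    "classify_table",
    "summarize",
    "q_estimate_range",
    "write_biom_json",
]

CATEGORIES = (
    "obligate_host",
    "preferential_host",
    "tied",
    "preferential_free",
    "obligate_free",
)


class OtuTable:
    """An OTU x sample incidence matrix.

    Built from a count table: present iff count > 0.  Duplicate ids and
    OTUs observed in no sample are rejected (drop the latter up front
    with ``drop_unobserved=True``).
    """

    def __init__(self, incidence: pd.DataFrame):
        if incidence.index.duplicated().any():
            dups = incidence.index[incidence.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if incidence.columns.duplicated().any():
            dups = incidence.columns[incidence.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        incidence = incidence.astype(bool)
        empty = incidence.index[~incidence.any(axis=1)].tolist()
        if empty:
            raise ValueError(
                f"{len(empty)} OTU(s) observed in no sample (e.g. {empty[:5]}); "
                "drop them with drop_unobserved=True"
            )
        self.incidence = incidence

    @property
    def otu_ids(self) -> pd.Index:
        return self.incidence.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.incidence.columns

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, drop_unobserved: bool = False) -> "OtuTable":
        inc = counts > 0
        if drop_unobserved:
            inc = inc.loc[inc.any(axis=1)]
        return cls(inc)

    @classmethod
    def from_tsv(cls, path: str | Path, drop_unobserved: bool = False) -> "OtuTable":
        """Read a TSV with OTU ids in the first column, samples across."""
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_counts(counts, drop_unobserved=drop_unobserved)

    @classmethod
    def from_biom_json(cls, path: str | Path, drop_unobserved: bool = False) -> "OtuTable":
        """Read a BIOM 1.0 (JSON) observation table, sparse or dense."""
        with open(path) as fh:
            doc = json.load(fh)
        otus = [row["id"] for row in doc["rows"]]
        samples = [col["id"] for col in doc["columns"]]
        n, m = doc["shape"]
        mat = np.zeros((n, m))
        if doc.get("matrix_type") == "dense":
            mat[:] = doc["data"]
        else:
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        counts = pd.DataFrame(mat, index=pd.Index(otus, name="otu_id"), columns=samples)
        return cls.from_counts(counts, drop_unobserved=drop_unobserved)

    def to_tsv(self, path: str | Path) -> None:
        out = self.incidence.astype(int)
        out.index.name = out.index.name or "otu_id"
        out.to_csv(path, sep="\t")


def write_biom_json(counts: pd.DataFrame, path: str | Path, table_id: str = "synthetic") -> None:
    """Write a count table as a minimal sparse BIOM 1.0 JSON document."""
    rows, cols = np.nonzero(counts.values)
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microdiv",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(counts.shape),
        "rows": [{"id": str(i), "metadata": None} for i in counts.index],
        "columns": [{"id": str(c), "metadata": None} for c in counts.columns],
        "data": [[int(i), int(j), int(counts.iat[i, j])] for i, j in zip(rows, cols)],
    }
    Path(path).write_text(json.dumps(doc))


@dataclass(frozen=True)
class SampleMetadata:
    """sample_id -> habitat label, with the free-living designation.

    Any label equal to ``free_living_label`` after trimming and case
    folding marks a non-host sample; every other label is host-derived.
    """

    habitat: pd.Series
    free_living_label: str = "Free-living"

    def __post_init__(self) -> None:
        if self.habitat.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        labels = self.habitat.astype(str).str.strip()
        if (labels == "").any():
            bad = self.habitat.index[labels == ""].tolist()
            raise ValueError(f"empty habitat labels for samples: {bad[:5]}")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample_column: str = "sample_id",
        habitat_column: str = "habitat",
        free_living_label: str = "Free-living",
    ) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in (sample_column, habitat_column):
            if col not in df.columns:
                raise ValueError(f"metadata file lacks column {col!r}; has {list(df.columns)}")
        series = df.set_index(sample_column)[habitat_column]
        return cls(series, free_living_label=free_living_label)

    def is_host(self) -> pd.Series:
        """Boolean per sample: True unless labeled free-living."""
        norm = self.habitat.astype(str).str.strip().str.casefold()
        return norm != self.free_living_label.strip().casefold()

    def to_tsv(self, path: str | Path) -> None:
        out = self.habitat.rename("habitat")
        out.index.name = "sample_id"
        out.reset_index().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class OtuFlags:
    host_any: bool
    host_preferential: bool
    host_obligate: bool
    free_any: bool
    free_preferential: bool
    free_obligate: bool

    @property
    def category(self) -> str:
        """Exclusive label matching the synthetic-mixture categories."""
        if self.host_obligate:
            return "obligate_host"
        if self.free_obligate:
            return "obligate_free"
        if self.host_preferential:
            return "preferential_host"
        if self.free_preferential:
            return "preferential_free"
        return "tied"


def classify_otu(host_occurrences: int, free_occurrences: int) -> OtuFlags:
    """Category flags for one OTU's occurrence split.

    Preferential requires strictly more than half of occurrences on the
    corresponding side, so an exact tie is preferential for neither.
    """
    h, f = int(host_occurrences), int(free_occurrences)
    if h < 0 or f < 0:
        raise ValueError(f"occurrence counts must be non-negative, got ({h}, {f})")
    total = h + f
    if total == 0:
        raise ValueError("OTU with zero occurrences cannot be classified")
    return OtuFlags(
        host_any=h >= 1,
        host_preferential=h * 2 > total,
        host_obligate=f == 0,
        free_any=f >= 1,
        free_preferential=f * 2 > total,
        free_obligate=h == 0,
    )


def _occurrence_counts(table: OtuTable, meta: SampleMetadata) -> pd.DataFrame:
    missing = table.sample_ids.difference(meta.habitat.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} sample(s) in the table missing from metadata: "
            f"{missing.tolist()[:10]}"
        )
    host_mask = meta.is_host().reindex(table.sample_ids).to_numpy()
    inc = table.incidence.to_numpy()
    return pd.DataFrame(
        {
            "host_occurrences": inc[:, host_mask].sum(axis=1),
            "free_occurrences": inc[:, ~host_mask].sum(axis=1),
        },
        index=table.otu_ids,
    )


def classify_table(table: OtuTable, meta: SampleMetadata) -> pd.DataFrame:
    """Per-OTU occurrence counts, flags, and exclusive category."""
    counts = _occurrence_counts(table, meta)
    h = counts["host_occurrences"].to_numpy()
    f = counts["free_occurrences"].to_numpy()
    total = h + f
    out = counts.copy()
    out["host_any"] = h >= 1
    out["host_preferential"] = h * 2 > total
    out["host_obligate"] = f == 0
    out["free_any"] = f >= 1
    out["free_preferential"] = f * 2 > total
    out["free_obligate"] = h == 0
    out["category"] = np.select(
        [f == 0, h == 0, h * 2 > total, f * 2 > total],
        ["obligate_host", "obligate_free", "preferential_host", "preferential_free"],
        default="tied",
    )
    return out


@dataclass(frozen=True)
class HostAssociationSummary:
    """Niche proportions (percent of all OTUs).

    The categories overlap by design — any-host and any-free OTUs are
    complementary to the opposite obligate class, so
    ``host_obligate + free_any == 100`` and symmetrically.
    """

    host_any: float
    host_preferential: float
    host_obligate: float
    free_any: float
    free_preferential: float
    free_obligate: float
    n_otus: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Host-associated", self.host_any),
            ("Preferentially host-associated", self.host_preferential),
            ("Obligate host-associated", self.host_obligate),
            ("Free-living", self.free_any),
            ("Preferentially free-living", self.free_preferential),
            ("Obligate free-living", self.free_obligate),
        ]
        return pd.DataFrame(rows, columns=["niche", "proportion_pct"])


def summarize(table: OtuTable, meta: SampleMetadata) -> HostAssociationSummary:
    """Niche proportions over every OTU in the table."""
    flags = classify_table(table, meta)
    n = len(flags)
    pct = lambda col: float(flags[col].mean() * 100.0)
    return HostAssociationSummary(
        host_any=pct("host_any"),
        host_preferential=pct("host_preferential"),
        host_obligate=pct("host_obligate"),
        free_any=pct("free_any"),
        free_preferential=pct("free_preferential"),
        free_obligate=pct("free_obligate"),
        n_otus=n,
    )


def q_estimate_range(summary: HostAssociationSummary) -> tuple[float, float]:
    """Bracketing vulnerable fractions for the mass-extinction model.

    The obligate host-associated proportion is the floor (only
    host-restricted taxa die with their hosts); the any-host proportion
    the ceiling (every taxon touching hosts is exposed).
    """
    return summary.host_obligate / 100.0, summary.host_any / 100.0
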