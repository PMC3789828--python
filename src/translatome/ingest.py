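"""Validated containers and TSV readers/writers for the pipeline's inputs.

The pipeline consumes gene-level count matrices from two assays — ribosome
footprints (RPF) and mRNA-seq — together with sample metadata (species,
condition, replicate), ortholog maps between species, and curated gene sets.

All on-disk formats are plain tab-separated UTF-8 text. Lines beginning with
``#`` are treated as comments and skipped. Count matrices carry the gene
identifier in a first column headed ``gene_id``; ortholog maps have one column
per species. Gene identifiers are opaque strings — no species-prefix parsing
is attempted, since the four nematode genomes use heterogeneous id schemes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSAYS = ("RPF", "mRNA")
CONDITIONS = ("diapause", "developing")

GENE_ID_COL = "gene_id"


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, negatives, ...)."""


class ParseError(ValueError):
    """A file could not be interpreted in the expected TSV dialect."""


def _check_assay(assay: str) -> str:
    if assay not in ASSAYS:
        raise ValidationError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    return assay


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts for one assay.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample id; row and column order is preserved from the source file.
    """

    counts: pd.DataFrame
    assay: str

    def __post_init__(self) -> None:
        _check_assay(self.assay)
        cdf = self.counts
        if cdf.index.has_duplicates:
            dups = cdf.index[cdf.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cdf.columns.has_duplicates:
            dups = cdf.columns[cdf.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if cdf.shape[0] < 1 or cdf.shape[1] < 2:
            raise ValidationError(
                f"count matrix needs >=1 gene and >=2 samples, got {cdf.shape}"
            )
        arr = cdf.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float input only if every cell is integral
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                bad = np.argwhere(~(np.isfinite(arr) & (arr == np.floor(arr))))
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {cdf.index[g]!r}, "
                    f"sample {cdf.columns[s]!r}: {arr[g, s]}"
                )
            cdf = cdf.astype(np.int64)
            object.__setattr__(self, "counts", cdf)
            arr = cdf.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {cdf.index[g]!r}, "
                f"sample {cdf.columns[s]!r}: {arr[g, s]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def read_count_matrix(path, assay: str) -> CountMatrix:
    """Read a TSV count matrix (first column ``gene_id``, header of samples)."""
    _check_assay(assay)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene_id column plus >=1 sample column")
    if df.columns[0] != GENE_ID_COL:
        raise ParseError(
            f"{path}: first column must be headed {GENE_ID_COL!r}, got {df.columns[0]!r}"
        )
    body = df.set_index(GENE_ID_COL)
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            gene = body.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-integer value at gene {gene!r}, sample {col!r}"
            )
        neg = vals < 0
        if neg.any():
            gene = body.index[neg.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: negative count at gene {gene!r}, sample {col!r}"
            )
        body[col] = vals.astype(np.int64)
    return CountMatrix(counts=body, assay=assay)


def write_count_matrix(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = GENE_ID_COL
    out.to_csv(path, sep="\t")


META_COLUMNS = ["sample_id", "species", "condition", "replicate", "assay"]


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table; returns a normalized copy.

    Required columns: sample_id, species, condition, replicate, assay.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"sample metadata missing columns: {missing}")
    meta = meta[META_COLUMNS].copy()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups[:5]}")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}")
    bad_assay = set(meta["assay"]) - set(ASSAYS)
    if bad_assay:
        raise ValidationError(f"unknown assays {sorted(bad_assay)}; expected {ASSAYS}")
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive integers")
    key = meta[["species", "condition", "replicate", "assay"]]
    if key.duplicated().any():
        raise ValidationError(
            "duplicate (species, condition, replicate, assay) combination in metadata"
        )
    return meta


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "species": str})
    return validate_sample_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    validate_sample_meta(meta).to_csv(path, sep="\t", index=False)


@dataclass
class GeneSet:
    """Named set of gene ids for one species (e.g. ribosomal proteins)."""

    name: str
    species: str
    gene_ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.gene_ids:
            raise ValidationError(f"gene set {self.name!r} ({self.species}) is empty")

    def restrict_to(self, gene_universe: Iterable[str]) -> "GeneSet":
        kept = self.gene_ids & set(gene_universe)
        if not kept:
            raise ValidationError(
                f"gene set {self.name!r} has no members in the supplied gene universe"
            )
        return GeneSet(self.name, self.species, kept)


def read_gene_set(path, name: str, species: str) -> GeneSet:
    """Read a one-id-per-line gene set file ('#' comments allowed)."""
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return GeneSet(name=name, species=species, gene_ids=frozenset(ids))


def write_gene_set(gs: GeneSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in sorted(gs.gene_ids):
            fh.write(f"{gid}\n")


@dataclass
class OrthologMap:
    """Pairwise links and four-way ortholog groups across species.

    ``fourway`` is a DataFrame with one column per species and one row per
    ortholog group (each species contributes exactly one gene per group).
    ``pairwise`` is a DataFrame with columns species_a/gene_a/species_b/gene_b;
    links are stored in both orientations (symmetric).
    """

    fourway: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species_a", "gene_a", "species_b", "gene_b"]
        )
    )

    def __post_init__(self) -> None:
        fw = self.fourway
        if len(fw):
            if fw.isna().any().any():
                raise ValidationError("four-way table has missing genes")
            for sp in fw.columns:
                col = fw[sp]
                if col.duplicated().any():
                    dup = col[col.duplicated()].iloc[0]
                    raise ValidationError(
                        f"gene {dup!r} appears in more than one four-way group "
                        f"for species {sp!r}"
                    )

    @property
    def species(self) -> list[str]:
        return list(self.fourway.columns)

    @property
    def n_groups(self) -> int:
        return len(self.fourway)

    def pairs(self, species_a: str, species_b: str) -> pd.DataFrame:
        """Ortholog gene pairs between two species (from four-way groups,
        supplemented by any explicit pairwise links)."""
        frames = []
        if species_a in self.fourway.columns and species_b in self.fourway.columns:
            frames.append(
                pd.DataFrame(
                    {"gene_a": self.fourway[species_a], "gene_b": self.fourway[species_b]}
                )
            )
        pw = self.pairwise
        sel = pw[(pw["species_a"] == species_a) & (pw["species_b"] == species_b)]
        if len(sel):
            frames.append(sel[["gene_a", "gene_b"]])
        if not frames:
            return pd.DataFrame(columns=["gene_a", "gene_b"])
        out = pd.concat(frames, ignore_index=True).drop_duplicates()
        return out.reset_index(drop=True)


def read_ortholog_map(fourway_path=None, pairwise_paths: Sequence | None = None) -> OrthologMap:
    """Load an ortholog map from a four-way TSV and/or pairwise TSVs.

    The four-way file has one column per species (header = species names) and
    one gene per cell. Pairwise files have two such columns. An empty file
    yields an empty (valid) map.
    """
    fourway = pd.DataFrame()
    if fourway_path is not None:
        try:
            fourway = pd.read_csv(fourway_path, sep="\t", comment="#", dtype=str)
        except pd.errors.EmptyDataError:
            fourway = pd.DataFrame()
        if fourway.shape[1] == 0 or fourway.shape[0] == 0:
            fourway = pd.DataFrame()
    rows = []
    for path in pairwise_paths or []:
        tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if tab.shape[1] != 2:
            raise ParseError(f"{path}: pairwise ortholog table needs exactly 2 columns")
        sp_a, sp_b = tab.columns
        for ga, gb in tab.itertuples(index=False):
            rows.append((sp_a, ga, sp_b, gb))
            rows.append((sp_b, gb, sp_a, ga))
    pairwise = pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b", "gene_b"])
    if not len(rows):
        pairwise = pd.DataFrame(columns=["species_a", "gene_a", "species_b", "gene_b"])
    return OrthologMap(fourway=fourway, pairwise=pairwise)


def write_ortholog_map(omap: OrthologMap, fourway_path) -> None:
    omap.fourway.to_csv(fourway_path, sep="\t", index=False)


@dataclass
class AlignedExperiment:
    """A count matrix joined with its metadata for one species and assay.

    Exposes, per condition, the replicate sample columns in replicate order.
    """

    cm: CountMatrix
    meta: pd.DataFrame  # indexed by sample_id, restricted to cm's samples
    species: str

    @property
    def assay(self) -> str:
        return self.cm.assay

    def condition_samples(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        sel = self.meta[self.meta["condition"] == condition]
        return list(sel.sort_values("replicate").index)

    def condition_counts(self, condition: str) -> pd.DataFrame:
        return self.cm.counts[self.condition_samples(condition)]


def align_samples(cm: CountMatrix, meta: pd.DataFrame) -> AlignedExperiment:
    """Join a count matrix with sample metadata of matching assay.

    Samples present in counts but absent from metadata are a hard error;
    metadata rows without a matching sample are dropped with a warning.
    """
    meta = validate_sample_meta(meta)
    meta = meta[meta["assay"] == cm.assay]
    known = set(meta["sample_id"])
    orphans = [s for s in cm.sample_ids if s not in known]
    if orphans:
        raise ValidationError(
            f"samples without metadata (assay {cm.assay}): {orphans}"
        )
    extra = sorted(known - set(cm.sample_ids))
    if extra:
        logger.warning(
            "metadata rows with no matching sample dropped: %s", extra
        )
        meta = meta[meta["sample_id"].isin(cm.sample_ids)]
    species = meta["species"].unique()
    if len(species) != 1:
        raise ValidationError(
            f"count matrix mixes species {sorted(species)}; supply one matrix per species"
        )
    meta = meta.set_index("sample_id").loc[cm.sample_ids]
    return AlignedExperiment(cm=cm, meta=meta, species=species[0])
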