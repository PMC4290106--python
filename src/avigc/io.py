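"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA ortholog alignments (one file per ortholog), Newick trees,
TSV-with-header tables for life-history traits, ortholog locations and
recombination windows (windows accepted in BED dialect: 0-based half-open).
Coordinates are 0-based half-open everywhere inside the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .trees import LabeledTree, tree_from_dendropy

logger = logging.getLogger(__name__)

# Nucleotide codes used package-wide. Ambiguity codes other than N are
# mapped to N (count logged); anything else is rejected.
A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5
ALPHABET = "ACGTN-"
_AMBIG = set(b"RYSWKMBDHV")

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _LUT[ord(_ch)] = _i
    _LUT[ord(_ch.lower())] = _i
for _b in _AMBIG:
    _LUT[_b] = N
    _LUT[ord(chr(_b).lower())] = N


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3,N=4,-=5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _LUT[raw]
    if (out == 255).any():
        bad = chr(raw[out == 255][0])
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass
class OrthologAlignment:
    """A per-ortholog multiple alignment, species id -> sequence.

    ``kind`` is ``coding`` (frame starts at column 0, length divisible by 3)
    or ``intron``. Sequences are stored uppercased over {A,C,G,T,N,-}.
    """

    ortholog_id: str
    kind: str
    sequences: dict[str, str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in ("coding", "intron"):
            raise ValueError(f"kind must be 'coding' or 'intron', got {self.kind!r}")
        if not self.sequences:
            raise ValueError(f"{self.ortholog_id}: empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            by_len = {sp: len(s) for sp, s in self.sequences.items()}
            raise ValueError(
                f"{self.ortholog_id}: ragged alignment, lengths {by_len}")
        (length,) = lengths
        if self.kind == "coding" and length % 3 != 0:
            raise ValueError(
                f"{self.ortholog_id}: coding alignment length {length} "
                "not divisible by 3")
        cleaned = {}
        n_ambig = 0
        alph = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
        ambig_arr = np.frombuffer(bytes(sorted(_AMBIG)), dtype=np.uint8)
        for sp, seq in self.sequences.items():
            raw = np.frombuffer(seq.upper().encode("ascii"),
                                dtype=np.uint8)
            codes = _LUT[raw]
            if (codes == 255).any():
                bad = chr(raw[codes == 255][0])
                raise ValueError(
                    f"{self.ortholog_id}/{sp}: invalid character {bad!r}")
            n_ambig += int(np.isin(raw, ambig_arr).sum())
            cleaned[sp] = alph[codes].tobytes().decode("ascii")
        if n_ambig:
            logger.info("%s: mapped %d ambiguity codes to N",
                        self.ortholog_id, n_ambig)
        self.sequences = cleaned

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def codes(self, species: list[str] | None = None) -> np.ndarray:
        """(n_species, length) uint8 matrix, rows in ``species`` order."""
        if species is None:
            if self._codes is None:
                self._codes = np.vstack(
                    [encode(self.sequences[sp]) for sp in self.sequences])
            return self._codes
        return np.vstack([encode(self.sequences[sp]) for sp in species])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_alignment(path, kind: str, ortholog_id: str | None = None,
                   name_map: dict | None = None) -> OrthologAlignment:
    """Read one ortholog alignment from FASTA.

    Species id is the header token before the first whitespace; an optional
    ``name_map`` translates header tokens to canonical species codes.
    """
    path = Path(path)
    if ortholog_id is None:
        ortholog_id = path.stem
    sequences = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = rec.id.split()[0]
        if name_map:
            sp = name_map.get(sp, sp)
        if sp in sequences:
            raise ValueError(f"{path}: duplicate species {sp!r}")
        sequences[sp] = str(rec.seq)
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return OrthologAlignment(ortholog_id=ortholog_id, kind=kind,
                             sequences=sequences)


def write_alignment(aln: OrthologAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp in aln.species:
            fh.write(f">{sp}\n{aln.sequences[sp]}\n")


def read_alignment_dir(directory, kind: str, pattern: str = "*.fa*",
                       name_map: dict | None = None) -> list[OrthologAlignment]:
    paths = sorted(Path(directory).glob(pattern))
    return [read_alignment(p, kind, name_map=name_map) for p in paths]


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_tree(path_or_string, length_units: str = "none",
              outgroup: str | None = None) -> LabeledTree:
    """Read a rooted Newick tree; internal-node labels become supports.

    Unrooted input (basal trifurcation) is rejected unless ``outgroup``
    names a tip to root on.
    """
    src = str(path_or_string)
    kwargs = dict(schema="newick", suppress_internal_node_taxa=True,
                  preserve_underscores=True)
    try:
        if src.lstrip().startswith("("):
            dtree = dendropy.Tree.get(data=src, **kwargs)
        else:
            dtree = dendropy.Tree.get(path=src, **kwargs)
    except dendropy.dataio.newickreader.NewickReader \
            .NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    if len(dtree.seed_node.child_nodes()) > 2:
        if outgroup is None:
            raise ValueError(
                "tree has a basal polytomy (unrooted); supply an outgroup "
                "to root it")
        og = dtree.find_node_with_taxon_label(outgroup.replace("_", " ")) or \
            dtree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not found in tree")
        dtree.reroot_at_edge(og.edge, update_bipartitions=False)
    return tree_from_dendropy(dtree, units=length_units)


def read_tree_dir(directory, length_units: str = "none",
                  pattern: str = "*.nwk") -> list[LabeledTree]:
    paths = sorted(Path(directory).glob(pattern))
    return [read_tree(p, length_units) for p in paths]


def write_tree(tree: LabeledTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = ["species", "body_mass_g", "max_longevity_yr",
                 "age_first_maturity_yr"]


def read_trait_table(path) -> pd.DataFrame:
    """Life-history traits, one row per species; missing values allowed.

    Columns: species, body_mass_g, max_longevity_yr, age_first_maturity_yr.
    All present values must be > 0.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns {sorted(missing)}")
    df = df[TRAIT_COLUMNS].copy()
    for col in TRAIT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise")
        bad = df.loc[df[col].notna() & (df[col] <= 0), "species"]
        if len(bad):
            raise ValueError(
                f"non-positive {col} for species {bad.tolist()}")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in trait table")
    return df.set_index("species", drop=False)


RECOMB_COLUMNS = ["chrom", "start", "end", "rate_cm_mb"]


def read_recomb_map(path, reference: str | None = None) -> pd.DataFrame:
    """Recombination map: fixed windows with cM/Mb rates (BED dialect,
    0-based half-open). Windows must be non-overlapping per chromosome."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""],
                     dtype={0: str})
    if list(df.columns[:4]) != RECOMB_COLUMNS:
        if df.shape[1] < 4:
            raise ValueError("recombination map needs 4 columns: "
                             f"{RECOMB_COLUMNS}")
        df.columns = RECOMB_COLUMNS + list(df.columns[4:])
    df = df[RECOMB_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"window end <= start at {bad['chrom']}:{bad['start']}")
    if (df["rate_cm_mb"] < 0).any():
        raise ValueError("negative recombination rate")
    for chrom, grp in df.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].values[1:] < g["end"].values[:-1]).any():
            raise ValueError(f"overlapping windows on chromosome {chrom}")
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    if reference is not None:
        df.attrs["reference"] = reference
    return df


LOCATION_COLUMNS = ["ortholog_id", "reference", "chrom", "start", "end"]


def read_locations(path) -> pd.DataFrame:
    """Ortholog -> reference-genome coordinates (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(LOCATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"locations table missing columns {sorted(missing)}")
    df = df[LOCATION_COLUMNS].copy()
    if (df["end"] <= df["start"]).any():
        raise ValueError("location end <= start")
    return df.sort_values(["reference", "ortholog_id"]).reset_index(drop=True)


def write_table(df: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    """Write a TSV with deterministic column and row order."""
    out = df.copy()
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_timespan_table(path) -> pd.DataFrame:
    """Internodal time spans (My) and node generation times (yr) keyed by
    branch id (the label of the branch's tipward node)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    required = {"branch_id", "time_span_my"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"timespan table missing columns {sorted(missing)}")
    return df
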