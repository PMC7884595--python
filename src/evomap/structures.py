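"""Domain types for structurally aligned tRNA gene sets.

The central objects are :class:`StructuralAlignment` (a fixed-width, 74-column
structural alignment of tRNA genes over the RNA alphabet), the Sprinzl
coordinate system that names its columns, the consensus secondary-structure
pairing of stem sites, and the nine-component structural partition used for
substitution-rate analysis.

Sprinzl coordinates are the standardized numbering of positions in the
consensus tRNA cloverleaf, which lets homologous sites be compared across
genes and species regardless of insertions.  The 74-column system used here
keeps the D-loop insertion "20A" as its own coordinate (shifting every later
label up by one, so the label "21" does not occur) and retains only
coordinates 45-49 of the variable arm; long variable arms (tRNA-Leu/Ser) are
excised before alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = ("A", "C", "G", "U")
GAP = "-"

#: Functional classes: the 20 amino-acid one-letter codes, "X" for initiator
#: tRNAs, and "?" for genes of indeterminate function.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
CLASS_ALPHABET = AMINO_ACIDS + ("X", "?")

#: Selenocysteine tRNAs are conventionally labelled "Z" in annotation tables;
#: they are dropped by default together with indeterminate genes.
SELENOCYSTEINE = "Z"

ALIGNMENT_WIDTH = 74


def _sprinzl_labels() -> tuple[str, ...]:
    labels = [str(i) for i in range(1, 21)]
    labels.append("20A")
    labels.extend(str(i) for i in range(22, 75))
    return tuple(labels)


@dataclass(frozen=True)
class SprinzlMap:
    """Ordered Sprinzl coordinate labels for the 74 alignment columns."""

    labels: tuple[str, ...] = field(default_factory=_sprinzl_labels)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("Sprinzl labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def column_of(self, label: str) -> int:
        """0-based alignment column for a Sprinzl label."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown Sprinzl label: {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels


#: Standard stem pairing in Sprinzl coordinates: acceptor stem 1:72..7:66,
#: D-stem 10:25..13:22, anticodon stem 27:43..31:39, T-stem 49:65..53:61.
STANDARD_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (str(a), str(b))
    for a, b in (
        [(i, 73 - i) for i in range(1, 8)]          # acceptor 1:72 .. 7:66
        + [(i, 35 - i) for i in range(10, 14)]      # D-stem 10:25 .. 13:22
        + [(i, 70 - i) for i in range(27, 32)]      # anticodon 27:43 .. 31:39
        + [(i, 114 - i) for i in range(49, 54)]     # T-stem 49:65 .. 53:61
    )
)


@dataclass(frozen=True)
class PairingTable:
    """Consensus secondary-structure pairing of stem sites."""

    pairs: tuple[tuple[str, str], ...] = STANDARD_PAIRS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            if a in seen or b in seen or a == b:
                raise ValueError(f"site appears in more than one pair: {a}:{b}")
            seen.update((a, b))

    @property
    def partner(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for a, b in self.pairs:
            out[a] = b
            out[b] = a
        return out

    def partner_of(self, site: str, sprinzl: SprinzlMap | None = None) -> str | None:
        """Pairing partner of ``site``, or ``None`` for loop sites."""
        sprinzl = sprinzl or SprinzlMap()
        if site not in sprinzl:
            raise KeyError(f"unknown Sprinzl label: {site!r}")
        return self.partner.get(site)


def _expand(*ranges: tuple[int, int]) -> tuple[str, ...]:
    out: list[str] = []
    for lo, hi in ranges:
        out.extend(str(i) for i in range(lo, hi + 1))
    return tuple(out)


#: Nine structural components used as rate partitions.  The D-loop spans
#: coordinates 14-22 which, in the 20A-inserted numbering, means
#: 14..20, 20A, 22 (there is no label "21").
RATE_PARTITIONS: dict[str, tuple[str, ...]] = {
    "acceptor stem": _expand((1, 7), (67, 73)),
    "D-stem": _expand((10, 13), (23, 26)),
    "D-loop": _expand((14, 20)) + ("20A",) + ("22",),
    "anticodon stem": _expand((28, 32), (40, 44)),
    "anticodon loop": _expand((33, 39)),
    "variable arm": _expand((45, 49)),
    "T-stem": _expand((50, 54), (62, 66)),
    "T-loop": _expand((55, 61)),
    "other": ("8", "9", "27", "74"),
}

#: Alternative partitioning in which the four stem components consist of
#: exactly the paired sites of :data:`STANDARD_PAIRS`; the loops absorb the
#: remainder.  This is the scheme consistent with the pairing convention and
#: is used when stems are modelled as 16-state doublets.
PAIRING_ALIGNED_PARTITIONS: dict[str, tuple[str, ...]] = {
    "acceptor stem": _expand((1, 7), (66, 72)),
    "D-stem": _expand((10, 13), (22, 25)),
    "D-loop": _expand((14, 20)) + ("20A",),
    "anticodon stem": _expand((27, 31), (39, 43)),
    "anticodon loop": _expand((32, 38)),
    "variable arm": _expand((44, 48)),
    "T-stem": _expand((49, 53), (61, 65)),
    "T-loop": _expand((54, 60)),
    "other": ("8", "9", "26", "73", "74"),
}


def structural_partitions(scheme: str = "rate") -> dict[str, tuple[str, ...]]:
    """The nine-component structural partition of the 74 Sprinzl sites.

    ``scheme="rate"`` returns the component ranges used for substitution-rate
    partitions; ``scheme="pairing"`` returns the variant whose stems are
    exactly the paired sites.
    """
    if scheme == "rate":
        return dict(RATE_PARTITIONS)
    if scheme == "pairing":
        return dict(PAIRING_ALIGNED_PARTITIONS)
    raise ValueError(f"unknown partition scheme: {scheme!r}")


@dataclass
class GeneRecord:
    """One aligned tRNA gene with its functional annotation.

    ``functional_class`` is an amino-acid one-letter code, "X" for initiator
    tRNAs, or "?" for indeterminate function.  ``cove_score`` is the
    covariance-model bit score used as a structural-quality filter.
    """

    gene_id: str
    aligned_seq: str
    species: str = ""
    functional_class: str = "?"
    anticodon: str = ""
    cove_score: float = 0.0
    ortholog_set_id: str | None = None
    chromosome: str | None = None
    anticodon_shift: bool = False
    pseudogene: bool = False

    def __post_init__(self) -> None:
        self.aligned_seq = normalize_seq(self.aligned_seq)
        if self.functional_class not in CLASS_ALPHABET + (SELENOCYSTEINE,):
            raise ValueError(
                f"{self.gene_id}: functional class {self.functional_class!r} "
                f"not in class alphabet"
            )
        if self.cove_score < 0:
            raise ValueError(f"{self.gene_id}: COVE score must be nonnegative")


def normalize_seq(seq: str) -> str:
    """Uppercase, T->U, and non-alphabet symbols (N, ambiguity codes) to gaps."""
    seq = seq.upper().replace("T", "U").replace(".", GAP)
    cleaned = []
    flagged = 0
    for ch in seq:
        if ch in RNA_ALPHABET or ch == GAP:
            cleaned.append(ch)
        else:
            cleaned.append(GAP)
            flagged += 1
    if flagged:
        logger.debug("normalized %d non-alphabet symbols to gaps", flagged)
    return "".join(cleaned)


@dataclass
class StructuralAlignment:
    """A fixed-width structural alignment of tRNA genes."""

    genes: list[GeneRecord]
    width: int = ALIGNMENT_WIDTH
    sprinzl: SprinzlMap = field(default_factory=SprinzlMap)

    def __post_init__(self) -> None:
        for g in self.genes:
            if len(g.aligned_seq) != self.width:
                raise ValueError(
                    f"{g.gene_id}: sequence length {len(g.aligned_seq)} != "
                    f"alignment width {self.width}"
                )
        if self.width != len(self.sprinzl):
            raise ValueError(
                f"width {self.width} != Sprinzl label count {len(self.sprinzl)}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def column(self, label: str) -> str:
        """Characters of all genes at one Sprinzl coordinate."""
        j = self.sprinzl.column_of(label)
        return "".join(g.aligned_seq[j] for g in self.genes)

    def subset(self, genes: Iterable[GeneRecord]) -> "StructuralAlignment":
        return StructuralAlignment(list(genes), self.width, self.sprinzl)

    def class_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            out[g.functional_class] = out.get(g.functional_class, 0) + 1
        return out


def read_alignment(path: str | Path, format: str = "fasta",
                   sprinzl: SprinzlMap | None = None) -> StructuralAlignment:
    """Read a FASTA or Stockholm alignment into a :class:`StructuralAlignment`.

    Gap symbols are normalized to "-" and T to U.  All sequences must have
    equal length; a custom :class:`SprinzlMap` may be supplied for widths
    other than 74.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        text = path.read_text() if path.exists() else ""
        if not text.strip():
            raise ValueError(f"empty alignment file: {path}") from exc
        raise ValueError(f"malformed or ragged alignment in {path}: {exc}") from exc
    if len(msa) == 0:
        raise ValueError(f"empty alignment file: {path}")
    width = msa.get_alignment_length()
    if sprinzl is None:
        sprinzl = SprinzlMap() if width == ALIGNMENT_WIDTH else SprinzlMap(
            tuple(str(i) for i in range(1, width + 1))
        )
    genes = [GeneRecord(gene_id=rec.id, aligned_seq=str(rec.seq)) for rec in msa]
    return StructuralAlignment(genes, width=width, sprinzl=sprinzl)


def write_alignment(aln: StructuralAlignment, path: str | Path,
                    format: str = "fasta") -> None:
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(g.aligned_seq), id=g.gene_id, description="")
        for g in aln.genes
    )
    AlignIO.write(msa, str(path), format)


ANNOTATION_COLUMNS = ("gene_id", "species", "class", "anticodon", "cove_score",
                      "ortholog_set", "chromosome")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-gene annotation table (TSV with header)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS[:5]) - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return table


def attach_annotations(aln: StructuralAlignment,
                       table: pd.DataFrame | str | Path) -> StructuralAlignment:
    """Populate gene metadata from an annotation table keyed by gene_id.

    Every gene in the alignment must have a matching row; unmatched table
    rows are reported in the log but tolerated.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_annotations(table)
    rows = {str(r["gene_id"]): r for _, r in table.iterrows()}
    genes = []
    for g in aln.genes:
        if g.gene_id not in rows:
            raise KeyError(f"no annotation row for gene {g.gene_id!r}")
        r = rows[g.gene_id]
        flags = str(r.get("flags", "") or "")
        genes.append(replace(
            g,
            species=str(r.get("species", "")),
            functional_class=str(r["class"]),
            anticodon=str(r.get("anticodon", "")),
            cove_score=float(r["cove_score"]),
            ortholog_set_id=str(r["ortholog_set"]) or None
            if "ortholog_set" in r else None,
            chromosome=str(r.get("chromosome", "")) or None,
            anticodon_shift="anticodon_shift" in flags,
            pseudogene="pseudogene" in flags,
        ))
    extra = set(rows) - {g.gene_id for g in aln.genes}
    if extra:
        logger.warning("%d annotation rows match no aligned gene", len(extra))
    return aln.subset(genes)


DEFAULT_DROP_CLASSES = frozenset({"?", SELENOCYSTEINE})


def filter_genes(aln: StructuralAlignment,
                 min_cove: float = 50.0,
                 drop_classes: frozenset[str] | set[str] = DEFAULT_DROP_CLASSES,
                 drop_anticodon_shift: bool = True,
                 drop_pseudogenes: bool = True) -> StructuralAlignment:
    """Quality-filter genes for structure-function analysis.

    Retains genes with COVE score >= ``min_cove`` (at-least semantics: a gene
    scoring exactly the threshold is kept), whose class is not in
    ``drop_classes`` (default: indeterminate "?" and selenocysteine), and that
    carry none of the dropped flags.
    """
    removed = {"cove": 0, "class": 0, "anticodon_shift": 0, "pseudogene": 0}
    kept = []
    for g in aln.genes:
        if g.cove_score < min_cove:
            removed["cove"] += 1
        elif g.functional_class in drop_classes:
            removed["class"] += 1
        elif drop_anticodon_shift and g.anticodon_shift:
            removed["anticodon_shift"] += 1
        elif drop_pseudogenes and g.pseudogene:
            removed["pseudogene"] += 1
        else:
            kept.append(g)
    for reason, n in removed.items():
        if n:
            logger.info("filter_genes: removed %d genes (%s)", n, reason)
    if not kept:
        logger.warning("filter_genes: no genes retained")
    return aln.subset(kept)


def partner_of(site: str) -> str | None:
    """Pairing partner of a Sprinzl site under the standard stem pairing."""
    return PairingTable().partner_of(site)
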