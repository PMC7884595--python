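"""Concatenated ortholog alignments, species-subset optimization, and
partitioned Bayesian rate-analysis support.

Ortholog sets of tRNA genes (one gene per species, inferred from flanking
micro-synteny) are concatenated into a single multi-species alignment.
Because species representation is uneven across sets, excluding
poorly-represented species can lengthen the gap-free concatenated alignment:
this module enumerates all species subsets above a minimum size, builds the
concatenation each subset induces (a set qualifies when its species coverage
is a superset of the subset), scores the alignments, and ranks the subsets.

It also writes partitioned NEXUS files (MrBayes 3.2 dialect) with either the
nine structural components or one partition per Sprinzl coordinate as
charsets, doublet (16-state) models on stems, a fixed topology, and the
sampling settings for the rate analysis; and it summarizes posterior samples
of per-partition rate multipliers (scaled so the mean rate over partitions
is 1.0 substitutions per site or site-pair) from MrBayes ".p" files.
"""

from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structures import (GAP, PairingTable, SprinzlMap, StructuralAlignment,
                         structural_partitions)

logger = logging.getLogger(__name__)


@dataclass
class OrthologSet:
    """One ortholog set: at most one member gene per species."""

    set_id: str
    members: dict[str, str]                 # species -> gene_id
    functional_class: str = "?"
    anticodon_shift: bool = False
    indeterminate: bool = False
    pseudogene: bool = False

    @property
    def flagged(self) -> bool:
        return self.anticodon_shift or self.indeterminate or self.pseudogene

    def covers(self, species: Iterable[str]) -> bool:
        return set(species) <= set(self.members)


def read_ortholog_sets(path: str | Path) -> list[OrthologSet]:
    """Read ortholog sets from TSV (set_id, species, gene_id, class, flags)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sets: dict[str, OrthologSet] = {}
    for _, r in table.iterrows():
        sid = str(r["set_id"])
        if sid not in sets:
            flags = str(r.get("flags", ""))
            sets[sid] = OrthologSet(
                sid, {}, functional_class=str(r.get("class", "?")),
                anticodon_shift="anticodon_shift" in flags,
                indeterminate="indeterminate" in flags,
                pseudogene="pseudogene" in flags)
        if str(r["species"]) in sets[sid].members:
            raise ValueError(f"set {sid}: duplicate species {r['species']}")
        sets[sid].members[str(r["species"])] = str(r["gene_id"])
    return list(sets.values())


@dataclass(frozen=True)
class SpeciesSubset:
    """An ordered species roster and a presence mask like "101111110000"."""

    roster: tuple[str, ...]
    mask: str

    def __post_init__(self) -> None:
        if len(self.mask) != len(self.roster):
            raise ValueError("mask length must equal roster length")
        if set(self.mask) - {"0", "1"}:
            raise ValueError("mask must be a bit string")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, bit in zip(self.roster, self.mask) if bit == "1")

    @property
    def size(self) -> int:
        return self.mask.count("1")

    @classmethod
    def from_species(cls, roster: Sequence[str],
                     species: Iterable[str]) -> "SpeciesSubset":
        chosen = set(species)
        return cls(tuple(roster), "".join("1" if s in chosen else "0"
                                          for s in roster))


def enumerate_subsets(roster: Sequence[str], min_size: int
                      ) -> list[SpeciesSubset]:
    """All species subsets of size >= min_size, in deterministic order
    (decreasing size, then combination order within size)."""
    n = len(roster)
    if not 1 <= min_size <= n:
        raise ValueError(f"min_size must be in [1, {n}], got {min_size}")
    out = []
    for size in range(n, min_size - 1, -1):
        for combo in itertools.combinations(range(n), size):
            mask = "".join("1" if i in combo else "0" for i in range(n))
            out.append(SpeciesSubset(tuple(roster), mask))
    return out


@dataclass
class AlignmentStats:
    n_sets: int
    total_sites: int
    gapfree_sites: int
    variable_sites: int
    pi_sites: int
    mean_pairwise_diff: float


@dataclass
class ConcatenatedAlignment:
    subset: SpeciesSubset
    rows: dict[str, str]                    # species -> concatenated sequence
    blocks: tuple[str, ...]                 # ordered ortholog-set ids
    site_partition: tuple[str, ...]         # column -> Sprinzl label

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def build_concatenation(sets: Sequence[OrthologSet],
                        aln: StructuralAlignment,
                        subset: SpeciesSubset) -> ConcatenatedAlignment:
    """Concatenate the ortholog sets whose species coverage includes the
    subset, restricted to the subset's species, blocks ordered by set_id.

    Flagged sets (anticodon shift, indeterminate, pseudogene) are excluded.
    Sets covering more species than the subset contribute only their subset
    rows, keeping the alignment rectangular.
    """
    species = subset.species
    gene_seq = {g.gene_id: g.aligned_seq for g in aln.genes}
    qualifying = sorted(
        (s for s in sets if not s.flagged and s.covers(species)),
        key=lambda s: s.set_id)
    if not qualifying:
        logger.warning("build_concatenation: no ortholog set covers subset %s",
                       subset.mask)
    rows = {sp: [] for sp in species}
    for s in qualifying:
        for sp in species:
            gid = s.members[sp]
            if gid not in gene_seq:
                raise KeyError(f"set {s.set_id}: gene {gid!r} not in alignment")
            rows[sp].append(gene_seq[gid])
    labels = aln.sprinzl.labels
    return ConcatenatedAlignment(
        subset=subset,
        rows={sp: "".join(parts) for sp, parts in rows.items()},
        blocks=tuple(s.set_id for s in qualifying),
        site_partition=labels * len(qualifying),
    )


def alignment_stats(c: ConcatenatedAlignment) -> AlignmentStats:
    """Site statistics of a concatenated alignment.

    Gap-free sites have no gap in any row; variable sites are gap-free sites
    with at least two states; parsimoniously informative sites are gap-free
    sites with at least two states each present in at least two rows.  The
    mean pairwise difference is the average, over row pairs, of the fraction
    of gap-free sites at which the pair differs.
    """
    if len(c.rows) < 2:
        raise ValueError("alignment statistics require at least two rows")
    mat = np.array([list(seq) for seq in c.rows.values()])
    n_rows, n_cols = mat.shape
    gapfree = ~(mat == GAP).any(axis=0)
    sub = mat[:, gapfree]
    variable = np.zeros(sub.shape[1], dtype=bool)
    informative = np.zeros(sub.shape[1], dtype=bool)
    for j in range(sub.shape[1]):
        states, counts = np.unique(sub[:, j], return_counts=True)
        variable[j] = states.size >= 2
        informative[j] = (counts >= 2).sum() >= 2
    n_gapfree = int(gapfree.sum())
    diffs = []
    for i, j in itertools.combinations(range(n_rows), 2):
        if n_gapfree:
            diffs.append(float((sub[i] != sub[j]).mean()))
        else:
            diffs.append(0.0)
    return AlignmentStats(
        n_sets=len(c.blocks),
        total_sites=n_cols,
        gapfree_sites=n_gapfree,
        variable_sites=int(variable.sum()),
        pi_sites=int(informative.sum()),
        mean_pairwise_diff=float(np.mean(diffs)) if diffs else 0.0,
    )


DEFAULT_RANK_KEYS = ("gapfree_sites", "n_sets", "pi_sites",
                     "mean_pairwise_diff")


def rank_subsets(stats: Mapping[str, AlignmentStats],
                 keys: Sequence[str] = DEFAULT_RANK_KEYS) -> pd.DataFrame:
    """Rank species subsets lexicographically by the given statistics,
    descending; returns the full metric table with a rank column."""
    if not stats:
        raise ValueError("no subsets to rank")
    rows = []
    for mask, st in stats.items():
        rows.append({"subset": mask, "n_species": mask.count("1"),
                     "n_sets": st.n_sets, "total_sites": st.total_sites,
                     "gapfree_sites": st.gapfree_sites,
                     "variable_sites": st.variable_sites,
                     "pi_sites": st.pi_sites,
                     "mean_pairwise_diff": st.mean_pairwise_diff})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(list(keys), ascending=False,
                              kind="mergesort").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


# ---------------------------------------------------------------------------
# Partitioned NEXUS generation

DEFAULT_MCMC = {"nruns": 2, "ngen": 4_000_000, "samplefreq": 500,
                "nchains": 4, "burninfrac": 0.25}


def write_partitioned_nexus(c: ConcatenatedAlignment,
                            scheme: str = "structural",
                            model: str = "gtr_i",
                            tree: str | None = None,
                            mcmc: Mapping[str, int | float] | None = None,
                            pairing: PairingTable | None = None) -> str:
    """Emit a partitioned NEXUS document in MrBayes 3.2 dialect.

    ``scheme`` is "structural" (nine charsets, one per structural component)
    or "per_site" (one charset per Sprinzl coordinate).  ``model`` is
    "gtr_i" (GTR with invariant sites everywhere), "gtr_i_g" (adds Gamma
    rate variation), or "doublet_gtr_i" (16-state doublet GTR+I on stems,
    nucleotide GTR+I on loops; stems then follow the pairing-aligned
    partition so charsets and pairs coincide).  The tree topology is fixed:
    topology moves are given zero proposal probability.  Rate multipliers
    are reported scaled so their mean over partitions is one.
    """
    if model not in ("gtr_i", "gtr_i_g", "doublet_gtr_i"):
        raise ValueError(f"unknown model: {model!r}")
    if scheme not in ("structural", "per_site"):
        raise ValueError(f"unknown partition scheme: {scheme!r}")
    settings = dict(DEFAULT_MCMC)
    settings.update(mcmc or {})
    pairing = pairing or PairingTable()
    ncols = c.length
    nblocks = len(c.blocks)
    width = len(SprinzlMap()) if nblocks == 0 else ncols // nblocks
    labels = c.site_partition

    # columns (1-based) per charset name
    if scheme == "per_site":
        charsets: dict[str, list[int]] = {}
        for j, lab in enumerate(labels):
            charsets.setdefault(f"sprinzl_{lab}", []).append(j + 1)
    else:
        part_scheme = "pairing" if model == "doublet_gtr_i" else "rate"
        parts = structural_partitions(part_scheme)
        label_to_part = {lab: name for name, labs in parts.items()
                         for lab in labs}
        charsets = {name: [] for name in parts}
        for j, lab in enumerate(labels):
            name = label_to_part.get(lab)
            if name is None:
                raise ValueError(f"column {j + 1} (Sprinzl {lab}) is not "
                                 f"covered by any partition")
            charsets[name].append(j + 1)
        charsets = {k: v for k, v in charsets.items() if v}

    def fmt_cols(cols: list[int]) -> str:
        # compress runs into NEXUS ranges
        runs, start, prev = [], cols[0], cols[0]
        for x in cols[1:]:
            if x == prev + 1:
                prev = x
                continue
            runs.append((start, prev))
            start = prev = x
        runs.append((start, prev))
        return " ".join(f"{a}-{b}" if b > a else f"{a}" for a, b in runs)

    def ident(name: str) -> str:
        return name.replace(" ", "_").replace("-", "_")

    out = io.StringIO()
    out.write("#NEXUS\n\nbegin data;\n")
    out.write(f"  dimensions ntax={len(c.rows)} nchar={ncols};\n")
    out.write("  format datatype=rna gap=- missing=?;\n  matrix\n")
    for sp, seq in c.rows.items():
        out.write(f"    {sp:<24s} {seq}\n")
    out.write("  ;\nend;\n\nbegin mrbayes;\n")
    if tree:
        out.write(f"  usertree = {tree.strip().rstrip(';')};\n")
    names = list(charsets)
    for name in names:
        out.write(f"  charset {ident(name)} = {fmt_cols(charsets[name])};\n")
    out.write(f"  partition {scheme} = {len(names)}: "
              + ", ".join(ident(n) for n in names) + ";\n")
    out.write(f"  set partition = {scheme};\n")
    if model == "doublet_gtr_i":
        pair_cols = []
        partner = pairing.partner
        label_col = {lab: i for i, lab in
                     enumerate(labels[:width])}
        for b in range(nblocks):
            off = b * width
            for a, bpart in pairing.pairs:
                pair_cols.append((off + label_col[a] + 1,
                                  off + label_col[bpart] + 1))
        out.write("  pairs " + ", ".join(f"{a}:{b}" for a, b in pair_cols)
                  + ";\n")
        stems = [i + 1 for i, n in enumerate(names) if "stem" in n]
        loops = [i + 1 for i, n in enumerate(names) if "stem" not in n]
        if stems:
            out.write(f"  lset applyto=({','.join(map(str, stems))}) "
                      "nucmodel=doublet nst=6 rates=propinv;\n")
        if loops:
            out.write(f"  lset applyto=({','.join(map(str, loops))}) "
                      "nucmodel=4by4 nst=6 rates=propinv;\n")
    else:
        rates = "invgamma" if model == "gtr_i_g" else "propinv"
        out.write(f"  lset applyto=(all) nst=6 rates={rates};\n")
    out.write("  prset applyto=(all) ratepr=variable;\n")
    out.write("  unlink statefreq=(all) revmat=(all) pinvar=(all);\n")
    if tree:
        out.write("  prset topologypr = fixed(usertree);\n")
    out.write("  propset ExtTBR$prob=0 NNI$prob=0 ParsSPR$prob=0 "
              "Multiplier$prob=0;\n")
    out.write("  report ratemult = scaled;\n")
    out.write(f"  mcmc nruns={settings['nruns']} nchains={settings['nchains']} "
              f"ngen={settings['ngen']} samplefreq={settings['samplefreq']} "
              f"burninfrac={settings['burninfrac']};\nend;\n")
    return out.getvalue()


def read_nexus_matrix(text: str) -> dict[str, str]:
    """Parse the data matrix back out of an emitted NEXUS document."""
    rows: dict[str, str] = {}
    in_matrix = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped == "matrix":
            in_matrix = True
            continue
        if in_matrix:
            if stripped == ";":
                break
            name, seq = stripped.split()
            rows[name] = rows.get(name, "") + seq
    return rows


# ---------------------------------------------------------------------------
# Posterior rate summarization

@dataclass
class RatePosteriorSummary:
    """Per-partition posterior summaries of scaled rate multipliers."""

    partitions: dict[str, dict[str, float]]
    n_samples: int

    def __getitem__(self, name: str) -> dict[str, float]:
        return self.partitions[name]


def read_param_samples(path: str | Path) -> pd.DataFrame:
    """Read a MrBayes ".p"-style tab-separated parameter-sample table,
    tolerating a leading "[ID: ...]" comment line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        skip = 1 if first.startswith("[") else 0
    return pd.read_csv(path, sep="\t", skiprows=skip)


def summarize_rate_posteriors(param_files: Sequence[str | Path],
                              burnin_frac: float = 0.25,
                              partition_names: Mapping[str, str] | None = None
                              ) -> RatePosteriorSummary:
    """Pool posterior samples across runs and summarize rate multipliers.

    The first ``burnin_frac`` of rows of each file is discarded as burn-in.
    Columns named like ``m{i}`` (MrBayes rate multipliers) are summarized by
    median, interquartile range, and central 95% credible interval;
    ``partition_names`` optionally maps column names to partition names.
    """
    if not 0 <= burnin_frac < 1:
        raise ValueError("burnin_frac must lie in [0, 1)")
    if not param_files:
        raise ValueError("no parameter files given")
    frames = []
    header: tuple[str, ...] | None = None
    for path in param_files:
        frame = read_param_samples(path)
        cols = tuple(frame.columns)
        if header is None:
            header = cols
        elif cols != header:
            raise ValueError(f"column headers of {path} do not match "
                             f"the first file")
        n_burn = int(np.floor(burnin_frac * len(frame)))
        frames.append(frame.iloc[n_burn:])
    pooled = pd.concat(frames, ignore_index=True)
    rate_cols = [col for col in pooled.columns
                 if col.startswith("m{") or col.startswith("m[")]
    if not rate_cols:
        rate_cols = [col for col in pooled.columns
                     if col not in ("Gen", "LnL", "LnPr", "TL")]
    partitions = {}
    for col in rate_cols:
        name = (partition_names or {}).get(col, col)
        vals = pooled[col].to_numpy(dtype=float)
        q = np.quantile(vals, [0.025, 0.25, 0.5, 0.75, 0.975])
        partitions[name] = {
            "median": float(q[2]), "iqr": float(q[3] - q[1]),
            "ci95_low": float(q[0]), "ci95_high": float(q[4]),
        }
    return RatePosteriorSummary(partitions, n_samples=len(pooled))
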