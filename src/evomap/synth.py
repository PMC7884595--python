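"""Synthetic tRNA gene-set generator with known ground truth.

Every other module is exercised against data from this generator, which
emulates the statistical structure of a re-annotated fly tRNA gene
complement without requiring any download: a fixed-width structural
alignment of ~290 genes across 22 functional classes, per-gene annotations,
planted class-informative features with controllable penetrance, per-taxon
modifications (for convergence scenarios such as a C17 identity co-option),
and ortholog sets with uneven species representation including a designed
low-coverage species and a species subset that dominates the concatenation
statistics.

The generator plants presence/absence structure only; it does not simulate
substitution processes down a phylogeny.  A mandatory seed drives one
documented pseudo-random stream, with sub-streams derived deterministically
per operation and per taxon so module tests are order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cif import SiteKey, site_name
from .concat_opt import OrthologSet
from .structures import (AMINO_ACIDS, GAP, RNA_ALPHABET, GeneRecord,
                         SprinzlMap, StructuralAlignment)

logger = logging.getLogger(__name__)

DEFAULT_CLASSES = AMINO_ACIDS + ("X", "Z")      # 22 functional classes
DEFAULT_ROSTER = tuple(f"sp{i:02d}" for i in range(1, 12))

#: Per-species probability that an ortholog set contains that species.
#: sp11 is the designed low-coverage species (a D. willistoni analogue);
#: sp08-sp10 are middling, so the subset excluding sp08..sp11 dominates.
DEFAULT_PRESENCE = {**{s: 0.95 for s in DEFAULT_ROSTER},
                    "sp08": 0.35, "sp09": 0.45, "sp10": 0.55, "sp11": 0.05}


@dataclass(frozen=True)
class PlantedCif:
    """A feature state imposed on the genes of given classes at a site."""

    site: SiteKey
    state: str
    classes: tuple[str, ...]
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        width = 2 if isinstance(self.site, tuple) else 1
        if len(self.state) != width:
            raise ValueError(f"state {self.state!r} does not match site "
                             f"{site_name(self.site)}")


@dataclass(frozen=True)
class TaxonMod:
    """Per-taxon deviation: extra plantings layered over the shared config."""

    name: str
    extra_plantings: tuple[PlantedCif, ...] = ()


@dataclass(frozen=True)
class SynthConfig:
    """Generative model for planted-CIF test data.  ``seed`` is mandatory."""

    seed: int
    classes: tuple[str, ...] = DEFAULT_CLASSES
    gene_copies: int | Mapping[str, int] = 13
    width: int = 74
    class_divergence: float = 0.2
    planted_cifs: tuple[PlantedCif, ...] = ()
    background_rate: float = 0.02
    gap_rate: float = 0.01
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    taxa: tuple[TaxonMod, ...] = ()
    species: str = "synth_sp"
    roster: tuple[str, ...] = DEFAULT_ROSTER
    n_ortholog_sets: int = 60
    presence_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRESENCE))

    def __post_init__(self) -> None:
        for rate in (self.class_divergence, self.background_rate,
                     self.gap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.size != 4 or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be 4 probabilities "
                             "summing to 1")
        _check_planting_conflicts(self.planted_cifs)
        for mod in self.taxa:
            _check_planting_conflicts(self.planted_cifs + mod.extra_plantings)

    def copies_of(self, cls: str) -> int:
        if isinstance(self.gene_copies, Mapping):
            return int(self.gene_copies.get(cls, 0))
        return int(self.gene_copies)


def _planting_columns(p: PlantedCif, sprinzl: SprinzlMap) -> list[int]:
    sites = p.site if isinstance(p.site, tuple) else (p.site,)
    return [sprinzl.column_of(s) for s in sites]


def _check_planting_conflicts(plantings: Sequence[PlantedCif]) -> None:
    sprinzl = SprinzlMap()
    assigned: dict[tuple[str, int], str] = {}
    for p in plantings:
        cols = _planting_columns(p, sprinzl)
        for cls in p.classes:
            for col, ch in zip(cols, p.state):
                key = (cls, col)
                if assigned.get(key, ch) != ch:
                    raise ValueError(
                        f"contradictory plantings for class {cls} at "
                        f"column {col}: {assigned[key]} vs {ch}")
                assigned[key] = ch


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


_BASES = np.array(list(RNA_ALPHABET))


def _draw_seq(rng: np.random.Generator, width: int,
              comp: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=width, p=comp)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            comp: np.ndarray) -> np.ndarray:
    """Replace each position with a draw from the composition, at ``rate``."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    out[hit] = rng.choice(4, size=int(hit.sum()), p=comp)
    return out


def simulate_gene_set(cfg: SynthConfig, taxon: str | None = None
                      ) -> tuple[StructuralAlignment, pd.DataFrame, pd.DataFrame]:
    """Simulate one taxon's aligned gene set with planted CIFs.

    Genes of each class derive from a class consensus (itself a divergence
    of a shared global consensus); planted states are imposed on target
    classes at their penetrance, background substitution noise and gaps are
    applied elsewhere.  Returns the alignment, an annotation table in the
    standard TSV layout, and a truth table listing every planted feature.
    Deterministic given the config seed (and taxon name).
    """
    sprinzl = SprinzlMap() if cfg.width == 74 else SprinzlMap(
        tuple(str(i) for i in range(1, cfg.width + 1)))
    taxon_mod = next((m for m in cfg.taxa if m.name == taxon), None)
    plantings = cfg.planted_cifs + (taxon_mod.extra_plantings if taxon_mod
                                    else ())
    stream = 0 if taxon is None else 1000 + sum(map(ord, taxon))
    rng = _rng(cfg, stream)
    comp = np.asarray(cfg.base_composition, dtype=float)

    base_idx = {b: i for i, b in enumerate(RNA_ALPHABET)}
    global_consensus = _draw_seq(rng, cfg.width, comp)
    planted_cols: dict[str, dict[int, int]] = {}      # class -> col -> base
    for p in plantings:
        cols = _planting_columns(p, sprinzl)
        for cls in p.classes:
            slot = planted_cols.setdefault(cls, {})
            for col, ch in zip(cols, p.state):
                slot[col] = base_idx[ch]

    # the shared consensus must not carry any planted state, and the
    # avoidance must be identical across classes — otherwise the planted
    # columns would acquire class-specific consensus bases and the planted
    # features would no longer be the only class signal
    forbidden_cols: set[int] = set()
    for p in plantings:
        cols = _planting_columns(p, sprinzl)
        forbidden_cols.update(cols)
        for col, ch in zip(cols, p.state):
            if global_consensus[col] == base_idx[ch]:
                alternatives = [i for i in range(4) if i != base_idx[ch]]
                global_consensus[col] = rng.choice(alternatives)

    class_consensus: dict[str, np.ndarray] = {}
    for cls in cfg.classes:
        cons = _mutate(rng, global_consensus, cfg.class_divergence, comp)
        # planted columns stay at the shared consensus for every class;
        # carriers are switched per gene below
        for col in forbidden_cols:
            cons[col] = global_consensus[col]
        class_consensus[cls] = cons

    genes: list[GeneRecord] = []
    ann_rows = []
    species = taxon or cfg.species
    chromosomes = np.array(["2L", "2R", "3L", "3R", "X"])
    for cls in cfg.classes:
        for copy in range(cfg.copies_of(cls)):
            seq = _mutate(rng, class_consensus[cls], cfg.background_rate, comp)
            chars = [_BASES[b] for b in seq]
            keep_cols = set(planted_cols.get(cls, {}))
            for p in plantings:
                if cls not in p.classes:
                    continue
                cols = _planting_columns(p, sprinzl)
                # one penetrance draw per planting: pair states are imposed
                # jointly or not at all
                if rng.random() < p.penetrance:
                    for col, ch in zip(cols, p.state):
                        chars[col] = ch
            if cfg.gap_rate > 0:
                gaps = rng.random(cfg.width) < cfg.gap_rate
                for j in np.nonzero(gaps)[0]:
                    if j not in keep_cols:
                        chars[j] = GAP
            gene_id = f"{species}_{cls}_{copy:03d}"
            cove = float(50.0 + 37.38 * rng.random())
            genes.append(GeneRecord(
                gene_id=gene_id, aligned_seq="".join(chars), species=species,
                functional_class=cls, anticodon="".join(
                    _BASES[rng.integers(0, 4, 3)]),
                cove_score=round(cove, 2),
                chromosome=str(rng.choice(chromosomes))))
            g = genes[-1]
            ann_rows.append({
                "gene_id": g.gene_id, "species": g.species, "class": cls,
                "anticodon": g.anticodon, "cove_score": g.cove_score,
                "ortholog_set": "", "chromosome": g.chromosome, "flags": ""})
    truth = pd.DataFrame([
        {"site": site_name(p.site), "state": p.state,
         "classes": ",".join(p.classes), "penetrance": p.penetrance}
        for p in plantings])
    aln = StructuralAlignment(genes, width=cfg.width, sprinzl=sprinzl)
    return aln, pd.DataFrame(ann_rows), truth


def simulate_taxa(cfg: SynthConfig) -> dict[
        str, tuple[StructuralAlignment, pd.DataFrame, pd.DataFrame]]:
    """Simulate every taxon named in ``cfg.taxa`` (order preserved)."""
    if not cfg.taxa:
        raise ValueError("config declares no taxa")
    return {m.name: simulate_gene_set(cfg, taxon=m.name) for m in cfg.taxa}


def simulate_ortholog_sets(cfg: SynthConfig
                           ) -> tuple[list[OrthologSet], StructuralAlignment]:
    """Simulate ortholog sets with uneven species representation.

    Each set has a consensus sequence; member genes are small mutational
    deviations of it, one per present species.  Species presence follows
    ``cfg.presence_probs``, which by default includes one very low-coverage
    species so that subsets excluding it concatenate many more sets.
    Returns the sets and a structural alignment holding every member gene.
    """
    rng = _rng(cfg, 1)
    sprinzl = SprinzlMap() if cfg.width == 74 else SprinzlMap(
        tuple(str(i) for i in range(1, cfg.width + 1)))
    comp = np.asarray(cfg.base_composition, dtype=float)
    probs = {s: cfg.presence_probs.get(s, 0.9) for s in cfg.roster}
    classes = list(cfg.classes)
    sets: list[OrthologSet] = []
    genes: list[GeneRecord] = []
    for i in range(cfg.n_ortholog_sets):
        sid = f"os{i:03d}"
        cons = _draw_seq(rng, cfg.width, comp)
        present = [s for s in cfg.roster if rng.random() < probs[s]]
        if not present:
            present = [cfg.roster[0]]
        members = {}
        cls = classes[int(rng.integers(0, len(classes)))]
        for sp in present:
            gid = f"{sid}_{sp}"
            seq = _mutate(rng, cons, cfg.background_rate, comp)
            genes.append(GeneRecord(
                gene_id=gid, aligned_seq="".join(_BASES[b] for b in seq),
                species=sp, functional_class=cls,
                cove_score=round(float(50 + 30 * rng.random()), 2),
                ortholog_set_id=sid))
            members[sp] = gid
        sets.append(OrthologSet(sid, members, functional_class=cls))
    aln = StructuralAlignment(genes, width=cfg.width, sprinzl=sprinzl)
    return sets, aln
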