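"""Class-Informative Feature (CIF) estimation.

A CIF is a nucleotide state (or, at stem sites, one of the sixteen ordered
base-pair / mis-pair states) at a Sprinzl coordinate whose presence carries
information about a tRNA gene's functional class.  The statistic is the
structure-conditioned functional information

    I(site, x) = H(Y) - H(Y | X_site = x)

in bits, where ``H(Y)`` is the background entropy of functional classes over
gene frequencies and ``H(Y | X_site = x)`` is the class entropy among the
genes carrying state ``x`` at that site, estimated with the NSB estimator
for features in two or more genes and the exact small-sample estimator for
singletons.  Negative differences (possible because NSB estimates can exceed
the background entropy) are clipped at zero: logo stack heights cannot be
negative.

Significance is assessed by a permutation test: for each feature, the class
labels of the genes bearing it are re-drawn without replacement from the
full class-label pool, and the information statistic recomputed.  Multiple
testing over all paired-site features is controlled with Benjamini-Hochberg
false discovery rates (Bonferroni family-wise control is available as an
alternative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .entropy import (CountVector, background_plugin_bits,
                      exact_small_sample_entropy, nsb_entropy, plugin_entropy)
from .structures import (GAP, RNA_ALPHABET, PairingTable, SprinzlMap,
                         StructuralAlignment)

logger = logging.getLogger(__name__)

SiteKey = str | tuple[str, str]

#: The sixteen ordered dinucleotide states of a paired site.
PAIR_STATES = tuple(a + b for a in RNA_ALPHABET for b in RNA_ALPHABET)


def site_name(site: SiteKey) -> str:
    return f"{site[0]}:{site[1]}" if isinstance(site, tuple) else site


def parse_site(name: str) -> SiteKey:
    if ":" in name:
        a, b = name.split(":")
        return (a, b)
    return name


@dataclass
class FeatureCountTable:
    """Per-state class counts n(x, y) at one site or site pair."""

    site: SiteKey
    states: tuple[str, ...]
    counts: dict[tuple[str, str], int]          # (state, class) -> genes
    class_totals: dict[str, int]
    missing: int = 0                            # genes gapped at the site

    def state_class_counts(self, state: str) -> dict[str, int]:
        return {y: n for (x, y), n in self.counts.items() if x == state and n > 0}

    def n_genes(self, state: str) -> int:
        return sum(self.state_class_counts(state).values())


@dataclass
class FunctionalInformation:
    """One CIF: a state at a site, its information and letter heights."""

    site: SiteKey
    state: str
    info: float
    n_genes: int
    heights: dict[str, float] = field(default_factory=dict)
    p_value: float | None = None
    q_value: float | None = None


@dataclass
class CifTable:
    taxon: str
    entries: list[FunctionalInformation]
    background: float
    gene_count: int

    def entry(self, site: SiteKey, state: str) -> FunctionalInformation | None:
        for e in self.entries:
            if e.site == site and e.state == state:
                return e
        return None


@dataclass
class ConvergenceProfile:
    family: str
    site: str
    per_taxon: dict[str, dict[str, int]]


# ---------------------------------------------------------------------------
# Counting and the information statistic

def background_entropy(class_totals: Mapping[str, int]) -> float:
    """Plug-in entropy (bits) of the gene-frequency distribution over classes."""
    totals = np.array([n for n in class_totals.values() if n > 0], dtype=float)
    if totals.size == 0:
        raise ValueError("no classes with genes")
    return background_plugin_bits(totals / totals.sum())


def count_features(aln: StructuralAlignment, site: SiteKey) -> FeatureCountTable:
    """Count genes by (state, class) at a single site or a site pair.

    Genes with a gap at any involved column are excluded from the table and
    tallied as missing.
    """
    if isinstance(site, tuple):
        cols = [aln.sprinzl.column_of(site[0]), aln.sprinzl.column_of(site[1])]
        states: tuple[str, ...] = PAIR_STATES
    else:
        cols = [aln.sprinzl.column_of(site)]
        states = RNA_ALPHABET
    counts: dict[tuple[str, str], int] = {}
    missing = 0
    for g in aln.genes:
        chars = [g.aligned_seq[j] for j in cols]
        if GAP in chars:
            missing += 1
            continue
        x = "".join(chars)
        key = (x, g.functional_class)
        counts[key] = counts.get(key, 0) + 1
    return FeatureCountTable(site, states, counts, aln.class_totals(), missing)


class _EntropyEngine:
    """Conditional-entropy evaluation with memoization on count multisets.

    The NSB and exact-small-sample estimates depend on the class-count vector
    only through its multiset of counts (given a fixed background), so
    permutation replicates can share results.
    """

    def __init__(self, class_totals: Mapping[str, int], estimator: str = "nsb"):
        self.classes = tuple(sorted(y for y, n in class_totals.items() if n > 0))
        totals = np.array([class_totals[y] for y in self.classes], dtype=float)
        self.bg = totals / totals.sum()
        self.k = len(self.classes)
        self.h_background = background_plugin_bits(self.bg)
        self.estimator = estimator
        self._cache: dict[tuple[int, ...], float] = {}

    def index(self, y: str) -> int:
        return self.classes.index(y)

    def conditional_entropy(self, counts: np.ndarray) -> float:
        key = tuple(sorted(int(c) for c in counts if c > 0))
        if key in self._cache:
            return self._cache[key]
        cv = CountVector(key, k=self.k)
        if self.estimator == "plugin":
            h = plugin_entropy(cv).value
        elif cv.n >= 2:
            h = nsb_entropy(cv).value
        else:
            h = exact_small_sample_entropy(cv, background=self.bg).value
        self._cache[key] = h
        return h

    def information(self, counts: np.ndarray) -> float:
        return max(0.0, self.h_background - self.conditional_entropy(counts))


def letter_heights(info: float,
                   class_cond_freqs: Mapping[str, float],
                   class_background_freqs: Mapping[str, float]
                   ) -> dict[str, float]:
    """Distribute a stack's information over classes by normalized log-odds.

    Each class receives weight ``max(0, log2(f(y|x) / f(y)))``; weights are
    renormalized so the heights sum to the stack information.  Classes at or
    below background frequency get zero height.  If no class is
    over-represented all heights are zero.
    """
    if info < 0:
        raise ValueError("information must be nonnegative")
    weights: dict[str, float] = {}
    for y, f_cond in class_cond_freqs.items():
        f_bg = class_background_freqs.get(y, 0.0)
        if f_cond > 0 and f_bg > 0:
            weights[y] = max(0.0, math.log2(f_cond / f_bg))
    total = sum(weights.values())
    if total == 0:
        return {y: 0.0 for y in class_cond_freqs}
    return {y: info * weights.get(y, 0.0) / total for y in class_cond_freqs}


def functional_information(fct: FeatureCountTable,
                           class_totals: Mapping[str, int] | None = None,
                           estimator: str = "nsb",
                           engine: _EntropyEngine | None = None
                           ) -> list[FunctionalInformation]:
    """Functional information for every state present at a site.

    ``class_totals`` defaults to the table's own background.  Entries are
    returned in state order; states carried by no gene are omitted.
    """
    totals = dict(class_totals or fct.class_totals)
    if engine is None:
        engine = _EntropyEngine(totals, estimator)
    bg_freq = {y: totals[y] / sum(totals.values()) for y in totals if totals[y] > 0}
    out: list[FunctionalInformation] = []
    for state in fct.states:
        by_class = fct.state_class_counts(state)
        n = sum(by_class.values())
        if n == 0:
            continue
        counts = np.zeros(engine.k)
        for y, c in by_class.items():
            counts[engine.index(y)] = c
        info = engine.information(counts)
        cond = {y: c / n for y, c in by_class.items()}
        heights = letter_heights(info, cond, bg_freq)
        out.append(FunctionalInformation(fct.site, state, info, n, heights))
    return out


# ---------------------------------------------------------------------------
# Permutation significance and multiple-testing control

def permutation_pvalues(aln: StructuralAlignment,
                        targets: Sequence[SiteKey],
                        B: int = 9999,
                        seed: int | None = None,
                        estimator: str = "nsb") -> dict[tuple[str, str], float]:
    """Permutation p-values for every observed feature at the target sites.

    For each (site, state) feature carried by ``n`` genes, the class labels
    of those genes are re-drawn without replacement from the full class-label
    pool ``B`` times, the information statistic recomputed each time, and

        p = (1 + #{I_perm >= I_obs}) / (B + 1).

    Deterministic given ``seed``.  Returns a mapping keyed by
    ``(site_name, state)``.
    """
    if B < 1:
        raise ValueError("permutation count B must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation tests")
    rng = np.random.default_rng(seed)
    engine = _EntropyEngine(aln.class_totals(), estimator)
    pool = np.array([engine.index(g.functional_class) for g in aln.genes])
    pvals: dict[tuple[str, str], float] = {}
    for site in targets:
        fct = count_features(aln, site)
        entries = functional_information(fct, engine=engine, estimator=estimator)
        for e in sorted(entries, key=lambda e: e.state):
            exceed = 0
            for _ in range(B):
                draw = rng.choice(pool, size=e.n_genes, replace=False)
                counts = np.bincount(draw, minlength=engine.k)
                if engine.information(counts) >= e.info:
                    exceed += 1
            pvals[(site_name(site), e.state)] = (1 + exceed) / (B + 1)
    return pvals


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(q, 1.0)


def bonferroni_fwer(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(p * p.size, 1.0)


def significant_cifs(table: CifTable, fdr: float = 0.05) -> CifTable:
    """Retain entries with q <= fdr (entries without a q-value are dropped)."""
    kept = [e for e in table.entries if e.q_value is not None and e.q_value <= fdr]
    return CifTable(table.taxon, kept, table.background, table.gene_count)


def estimate_cifs(aln: StructuralAlignment,
                  taxon: str = "",
                  include_singles: bool = True,
                  include_pairs: bool = True,
                  estimator: str = "nsb",
                  permutations: int = 0,
                  seed: int | None = None,
                  permute_singles: bool = False,
                  pairing: PairingTable | None = None) -> CifTable:
    """Estimate the full CIF table for one taxon's aligned gene set.

    Paired-site features use the sixteen ordered dinucleotide states over the
    standard stem pairing.  When ``permutations`` > 0, permutation p-values
    and BH q-values are attached — by default for paired-site features only,
    which form one multiple-testing family.
    """
    pairing = pairing or PairingTable()
    engine = _EntropyEngine(aln.class_totals(), estimator)
    background = engine.h_background
    targets: list[SiteKey] = []
    if include_singles:
        targets.extend(aln.sprinzl.labels)
    if include_pairs:
        targets.extend(pairing.pairs)
    entries: list[FunctionalInformation] = []
    for site in targets:
        fct = count_features(aln, site)
        entries.extend(functional_information(fct, engine=engine,
                                              estimator=estimator))
    if permutations > 0:
        perm_targets = [t for t in targets
                        if isinstance(t, tuple) or permute_singles]
        pvals = permutation_pvalues(aln, perm_targets, B=permutations,
                                    seed=seed, estimator=estimator)
        keyed = [(i, e) for i, e in enumerate(entries)
                 if (site_name(e.site), e.state) in pvals]
        ps = [pvals[(site_name(e.site), e.state)] for _, e in keyed]
        qs = bh_fdr(ps) if ps else []
        for (i, e), p, q in zip(keyed, ps, qs):
            entries[i] = replace(e, p_value=float(p), q_value=float(q))
    return CifTable(taxon, entries, background, len(aln))


# ---------------------------------------------------------------------------
# Output: function logos and tables

_TEXT_COLUMNS = ["taxon", "site", "state", "n", "info_bits", "heights", "p", "q"]


def cif_table_to_frame(table: CifTable) -> pd.DataFrame:
    rows = []
    for e in table.entries:
        heights = ",".join(f"{y}:{h:.9g}" for y, h in sorted(e.heights.items())
                           if h > 0)
        rows.append({
            "taxon": table.taxon, "site": site_name(e.site), "state": e.state,
            "n": e.n_genes, "info_bits": f"{e.info:.9g}", "heights": heights,
            "p": "" if e.p_value is None else f"{e.p_value:.9g}",
            "q": "" if e.q_value is None else f"{e.q_value:.9g}",
        })
    return pd.DataFrame(rows, columns=_TEXT_COLUMNS)


def _frame_to_cif_table(frame: pd.DataFrame, background: float,
                        gene_count: int) -> CifTable:
    entries = []
    taxon = ""
    for _, r in frame.iterrows():
        taxon = str(r["taxon"])
        heights = {}
        if str(r["heights"]):
            for item in str(r["heights"]).split(","):
                y, h = item.split(":")
                heights[y] = float(h)
        entries.append(FunctionalInformation(
            parse_site(str(r["site"])), str(r["state"]), float(r["info_bits"]),
            int(r["n"]), heights,
            p_value=float(r["p"]) if str(r["p"]) else None,
            q_value=float(r["q"]) if str(r["q"]) else None,
        ))
    return CifTable(taxon, entries, background, gene_count)


def render_function_logo(table: CifTable, format: str = "text") -> str:
    """Render a CIF table as a function logo (svg) or statistics table (text).

    In the text format each row lists site, state, gene count, information,
    per-class letter heights, and permutation p / BH q where available; the
    header carries the background entropy and gene count so the document
    round-trips to an identical table via :func:`read_cif_table`.
    """
    if not table.entries:
        raise ValueError("cannot render an empty CIF table")
    if format == "text":
        frame = cif_table_to_frame(table)
        header = (f"# background_bits={table.background:.9g}\t"
                  f"gene_count={table.gene_count}\n")
        return header + frame.to_csv(sep="\t", index=False)
    if format == "svg":
        return _render_svg(table)
    raise ValueError(f"unknown logo format: {format!r}")


def read_cif_table(text: str) -> CifTable:
    """Parse the text logo format back into a :class:`CifTable`."""
    lines = text.splitlines()
    background, gene_count = 0.0, 0
    if lines and lines[0].startswith("#"):
        for token in lines[0][1:].split("\t"):
            key, val = token.strip().split("=")
            if key == "background_bits":
                background = float(val)
            elif key == "gene_count":
                gene_count = int(val)
        lines = lines[1:]
    from io import StringIO
    frame = pd.read_csv(StringIO("\n".join(lines)), sep="\t", dtype=str,
                        keep_default_na=False)
    return _frame_to_cif_table(frame, background, gene_count)


def _render_svg(table: CifTable, px_per_bit: float = 40.0,
                col_width: float = 22.0) -> str:
    """Minimal SVG function logo: one column per (site, state), letters
    scaled to their heights, stack height equal to the information."""
    entries = sorted((e for e in table.entries if e.info > 0),
                     key=lambda e: (site_name(e.site), e.state))
    max_bits = max((e.info for e in entries), default=1.0)
    height = max_bits * px_per_bit + 60
    width = col_width * max(len(entries), 1) + 40
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}">',
        f'<text x="5" y="15" font-size="11">{table.taxon} function logo '
        f'(H(Y) = {table.background:.3f} bits, n = {table.gene_count})</text>',
    ]
    palette = {"X": "#7f3fbf"}
    for i, e in enumerate(entries):
        x = 25 + i * col_width
        y = height - 30
        for y_class, h in sorted(e.heights.items(), key=lambda kv: kv[1]):
            if h <= 0:
                continue
            hpx = h * px_per_bit
            color = palette.get(y_class, "#1f4e9c")
            parts.append(
                f'<text x="{x:.1f}" y="{y:.1f}" font-family="monospace" '
                f'font-size="16" fill="{color}" transform="translate(0,0)" '
                f'textLength="{col_width - 6:.1f}" '
                f'lengthAdjust="spacingAndGlyphs" '
                f'style="font-size:16px" dy="0" '
                f'data-height-bits="{h:.6f}">{y_class}</text>'
            )
            parts.append(
                f'<rect x="{x - 2:.1f}" y="{y - hpx:.1f}" width="2" '
                f'height="{hpx:.1f}" fill="{color}" opacity="0.35"/>'
            )
            y -= hpx
        parts.append(
            f'<text x="{x:.1f}" y="{height - 14:.1f}" font-size="8" '
            f'transform="rotate(45 {x:.1f} {height - 14:.1f})">'
            f'{site_name(e.site)} {e.state}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# Cross-taxon conservation and convergence

def convergence_profile(alns: Mapping[str, StructuralAlignment],
                        family: str, site: str) -> ConvergenceProfile:
    """Per-taxon state counts at one site among genes of one functional class.

    Counts (including gaps) sum to the taxon's family gene count; taxa
    lacking the family get a zero row and a log message.
    """
    per_taxon: dict[str, dict[str, int]] = {}
    for taxon, aln in alns.items():
        fam = [g for g in aln.genes if g.functional_class == family]
        if not fam:
            logger.info("convergence_profile: class %s absent in %s",
                        family, taxon)
            per_taxon[taxon] = {}
            continue
        j = aln.sprinzl.column_of(site)
        counts: dict[str, int] = {}
        for g in fam:
            ch = g.aligned_seq[j]
            counts[ch] = counts.get(ch, 0) + 1
        per_taxon[taxon] = counts
    return ConvergenceProfile(family, site, per_taxon)


def compare_cif_tables(tables: Mapping[str, CifTable],
                       site: SiteKey, state: str,
                       outgroup: str | None = None) -> pd.DataFrame:
    """Evolutionary polarization of one feature across taxa.

    For each taxon, reports the top-associated class (the class with the
    largest letter height at the feature) and flags taxa whose top class
    differs from the designated outgroup's (default: first taxon).
    """
    if len(tables) < 2:
        raise ValueError("need at least two taxa to compare")
    taxa = list(tables)
    outgroup = outgroup or taxa[0]
    if outgroup not in tables:
        raise KeyError(f"outgroup {outgroup!r} not among taxa")

    def top_class(table: CifTable) -> tuple[str | None, float]:
        e = table.entry(site, state)
        if e is None or not e.heights:
            return None, 0.0
        y, h = max(e.heights.items(), key=lambda kv: kv[1])
        return (y if h > 0 else None), h

    ref_class, _ = top_class(tables[outgroup])
    rows = []
    for taxon in taxa:
        y, h = top_class(tables[taxon])
        rows.append({"taxon": taxon, "site": site_name(site), "state": state,
                     "top_class": y or "", "top_height_bits": h,
                     "differs_from_outgroup": y != ref_class})
    return pd.DataFrame(rows)
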