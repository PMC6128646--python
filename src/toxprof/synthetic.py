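"""Synthetic data with the statistical structure of a pooled fitness screen.

Generates everything the downstream analysis consumes, so the whole pipeline
is testable without sequencing data: barcoded deletion pools grown
competitively under control and treatment conditions, FASTQ reads with
substitution errors, random term annotations with an optionally planted
enrichment signal, and flow-cytometry event tables mixing GFP+ / GFP- live
singlets with dead cells, doublets and debris.

Growth model
------------
Each mutant i has a latent relative growth rate rho_i in [0, 1]: the fraction
of the pool's doublings it achieves under treatment (rho=1 neutral, rho=0 no
growth). Over g pool doublings the treated abundance of mutant i is
proportional to a0_i * 2**(g*rho_i) while the control is proportional to
a0_i * 2**g. For a mutant at trace abundance the growth-inhibition score
computed downstream is then 1 - rho, which puts a completely non-growing
mutant at GI ~ 1 and a neutral one exactly at 0. Randomness enters only at
read sampling (multinomial across strains, i.i.d. base substitutions within
reads) — the pool dynamics themselves are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .barcodes import BarcodeLibrary
from .enrichment import AnnotationSet

__all__ = [
    "PoolSimConfig",
    "ReadSimConfig",
    "FlowSimConfig",
    "PlantedTerm",
    "simulate_pool",
    "simulate_screen_counts",
    "simulate_reads",
    "simulate_annotations",
    "simulate_flow_events",
    "random_library",
    "write_fastq",
    "competition_fractions",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# pool growth


@dataclass
class PoolSimConfig:
    """Conditions of a pooled competitive-growth experiment.

    relative_growth_rates (rho) default to all-neutral; initial_abundances
    default to uniform and are renormalized to sum to 1. pool_doublings
    defaults to 5, the depth of selective growth used for the screens this
    generator emulates.
    """

    n_mutants: int
    relative_growth_rates: np.ndarray | None = None
    initial_abundances: np.ndarray | None = None
    pool_doublings: float = 5.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")
        if self.relative_growth_rates is None:
            self.relative_growth_rates = np.ones(self.n_mutants)
        self.relative_growth_rates = np.asarray(self.relative_growth_rates, dtype=float)
        if self.relative_growth_rates.shape != (self.n_mutants,):
            raise ValueError("relative_growth_rates must have length n_mutants")
        rho = self.relative_growth_rates
        if not np.all(np.isfinite(rho)) or rho.min() < 0 or rho.max() > 1:
            raise ValueError("relative growth rates must be finite and in [0, 1]")
        if self.initial_abundances is None:
            self.initial_abundances = np.full(self.n_mutants, 1.0 / self.n_mutants)
        a0 = np.asarray(self.initial_abundances, dtype=float)
        if a0.shape != (self.n_mutants,):
            raise ValueError("initial_abundances must have length n_mutants")
        if not np.all(np.isfinite(a0)) or a0.min() <= 0:
            raise ValueError("initial abundances must be finite and positive")
        self.initial_abundances = a0 / a0.sum()
        if not (self.pool_doublings > 0 and np.isfinite(self.pool_doublings)):
            raise ValueError("pool_doublings must be positive and finite")


def simulate_pool(config: PoolSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free endpoint abundances (control, treatment), each summing to 1.

    Treatment abundance of mutant i is proportional to a0_i * 2**(g*rho_i);
    control to a0_i * 2**g (so control frequencies equal the normalized
    initial abundances — every mutant doubles g times without selection).
    """
    a0 = config.initial_abundances
    g = config.pool_doublings
    rho = config.relative_growth_rates
    with np.errstate(over="ignore"):
        control = a0 * np.exp2(np.float64(g))
        treatment = a0 * np.exp2(g * rho)
    if not (np.all(np.isfinite(control)) and np.all(np.isfinite(treatment))):
        raise ValueError("non-finite abundances; reduce pool_doublings")
    return control / control.sum(), treatment / treatment.sum()


def simulate_screen_counts(
    config: PoolSimConfig,
    depth: int,
    rng: np.random.Generator,
    rho_jitter_sigma: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """One screen's (control, treatment) read counts at the given depth.

    Biological replicate-to-replicate variability is modeled as log-normal
    jitter on rho (multiplicative, sigma on the log scale, clipped back to
    [0, 1]); sequencing sampling is multinomial at ``depth`` reads. Pass
    ``rho_jitter_sigma=0`` for a pure-multinomial screen.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rho = config.relative_growth_rates
    if rho_jitter_sigma > 0:
        rho = np.clip(rho * rng.lognormal(0.0, rho_jitter_sigma, rho.shape), 0.0, 1.0)
    jittered = PoolSimConfig(
        n_mutants=config.n_mutants,
        relative_growth_rates=rho,
        initial_abundances=config.initial_abundances,
        pool_doublings=config.pool_doublings,
    )
    control, treatment = simulate_pool(jittered)
    return rng.multinomial(depth, control), rng.multinomial(depth, treatment)


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSimConfig:
    """Sequencing layout and error model for barcode reads.

    The read is ``flank5 + barcode + flank3``; substitutions are applied
    i.i.d. per base at ``substitution_error_rate``. The platform this
    emulates produced short single-end reads, so the default layout keeps
    the barcode near the read start behind a short fixed flank.
    """

    depth: int
    substitution_error_rate: float = 0.0
    flank5: str = "TCGACGGATC"
    flank3: str = "CGTACGCTGC"
    quality_char: str = "I"
    seed: int | None = None

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.substitution_error_rate < 0.25):
            raise ValueError("substitution_error_rate must be in [0, 0.25)")

    @property
    def barcode_offset(self) -> int:
        return len(self.flank5)


def simulate_reads(
    abundances: np.ndarray,
    library: BarcodeLibrary,
    config: ReadSimConfig,
) -> tuple[list, np.ndarray]:
    """Multinomial read sampling with i.i.d. substitution errors.

    Returns ``(records, true_counts)`` where ``records`` are Biopython
    SeqRecords in shuffled order and ``true_counts`` is the realized
    multinomial draw per library entry (so exact-recovery checks do not
    have to re-derive it). Warns if two library barcodes lie within
    Hamming distance 2 of each other — substitution errors could then
    move a read from one strain's barcode onto another's.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    abundances = np.asarray(abundances, dtype=float)
    if abundances.shape != (len(library.frame),):
        raise ValueError("abundances must align with the library entries")
    if library.min_pairwise_distance() <= 2:
        warnings.warn(
            "library contains barcodes within Hamming distance 2 of each "
            "other; error-tolerant matching may cross-assign reads",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    counts = rng.multinomial(config.depth, abundances / abundances.sum())

    templates = [
        config.flank5 + bc + config.flank3 for bc in library.frame["barcode"]
    ]
    L = len(templates[0])
    # one uint8 matrix of all reads, then vectorized substitution errors
    reads = np.empty((config.depth, L), dtype=np.uint8)
    row = 0
    origins = np.empty(config.depth, dtype=int)
    for i, (tpl, c) in enumerate(zip(templates, counts)):
        if c:
            reads[row : row + c] = np.frombuffer(tpl.encode(), dtype=np.uint8)
            origins[row : row + c] = i
            row += c
    e = config.substitution_error_rate
    if e > 0:
        mask = rng.random(reads.shape) < e
        n_err = int(mask.sum())
        # substitute with a uniformly chosen *different* base
        shifts = rng.integers(1, 4, size=n_err)
        idx = np.searchsorted(_BASES, reads[mask])
        idx[idx >= 4] = 0  # N in a flank/barcode: replace from A's cycle
        reads[mask] = _BASES[(idx + shifts) % 4]
    order = rng.permutation(config.depth)
    qual = [ord(config.quality_char) - 33] * L
    ids = library.frame["mutant_id"].tolist()
    records = []
    for j, r in enumerate(order):
        rec = SeqRecord(
            Seq(reads[r].tobytes().decode()),
            id=f"read{j}|{ids[origins[r]]}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    return records, counts


def write_fastq(records, path) -> None:
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def random_library(
    n: int,
    length: int = 20,
    seed: int | None = None,
    min_distance: int = 3,
    gene_prefix: str = "gene",
) -> BarcodeLibrary:
    """Random barcode library with a guaranteed minimum pairwise distance."""
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, length), dtype=np.uint8)
    k = 0
    attempts = 0
    while k < n:
        cand = _BASES[rng.integers(0, 4, size=length)]
        if k == 0 or (accepted[:k] != cand).sum(axis=1).min() >= min_distance:
            accepted[k] = cand
            k += 1
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not place barcodes at the requested distance")
    width = len(str(n))
    frame = pd.DataFrame(
        {
            "mutant_id": [f"mut{i + 1:0{width}d}" for i in range(n)],
            "barcode": [accepted[i].tobytes().decode() for i in range(n)],
            "gene": [f"{gene_prefix}{i + 1:0{width}d}" for i in range(n)],
        }
    )
    return BarcodeLibrary(frame)


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class PlantedTerm:
    """A term with a controlled overlap into a designated gene list."""

    term_id: str
    list_genes: tuple
    overlap: int
    term_size: int


def simulate_annotations(
    genes: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    planted_term: PlantedTerm | None = None,
    seed: int | None = None,
) -> AnnotationSet:
    """Random term memberships over ``genes``, optionally with one planted term.

    The planted term contains exactly ``overlap`` genes from
    ``planted_term.list_genes`` plus fillers from outside that list, so the
    list is enriched for it at a known, controllable strength.
    """
    genes = list(genes)
    lo, hi = term_size_range
    if lo < 1:
        raise ValueError("term sizes must be >= 1")
    if hi > len(genes):
        raise ValueError("term sizes must not exceed the background size")
    rng = np.random.default_rng(seed)
    terms: dict[str, frozenset] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"term{t + 1:04d}"] = frozenset(rng.choice(genes, size=size, replace=False))
    if planted_term is not None:
        pool = list(planted_term.list_genes)
        if planted_term.term_size < 1:
            raise ValueError("planted term size must be >= 1")
        if planted_term.overlap > min(len(pool), planted_term.term_size):
            raise ValueError("planted overlap exceeds the list or the term size")
        if not set(pool) <= set(genes):
            raise ValueError("planted list genes must belong to the background")
        inside = rng.choice(pool, size=planted_term.overlap, replace=False)
        outside_pool = [g for g in genes if g not in set(pool)]
        n_fill = planted_term.term_size - planted_term.overlap
        if n_fill > len(outside_pool):
            raise ValueError("not enough background genes outside the list to fill the term")
        fill = rng.choice(outside_pool, size=n_fill, replace=False)
        terms[planted_term.term_id] = frozenset(inside) | frozenset(fill)
    return AnnotationSet(terms=terms, background=frozenset(genes))


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass
class FlowSimConfig:
    """Mixture model for competitive-growth flow-cytometry samples.

    Event classes: GFP+ wild type, GFP- competitor, dead (DAPI-permeable)
    cells, doublets and debris; ``fractions`` maps class name to its share
    of events (renormalized if the shares sum to < 1). FITC intensities are
    drawn log10-normally per GFP cluster; the two cluster medians must be
    at least one decade apart or the GFP gate is meaningless.
    ``gfp_loss_rate`` is the fraction of GFP+ cells whose fluorescence has
    silenced — they emit GFP- intensities but keep a distinguishing truth
    label. Observed loss rates in this assay class run about 0.1–1%.
    """

    n_events: int
    fractions: dict = field(
        default_factory=lambda: {
            "gfp_pos": 0.47,
            "gfp_neg": 0.47,
            "dead": 0.02,
            "doublet": 0.02,
            "debris": 0.02,
        }
    )
    fitc_pos_log_mean: float = 4.0
    fitc_pos_log_sd: float = 0.2
    fitc_neg_log_mean: float = 1.0
    fitc_neg_log_sd: float = 0.3
    gfp_loss_rate: float = 0.003
    seed: int | None = None

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        known = {"gfp_pos", "gfp_neg", "dead", "doublet", "debris"}
        if set(self.fractions) - known:
            raise ValueError(f"unknown event classes: {set(self.fractions) - known}")
        fr = {k: float(self.fractions.get(k, 0.0)) for k in known}
        if any(not (0.0 <= v <= 1.0) for v in fr.values()):
            raise ValueError("fractions must lie in [0, 1]")
        total = sum(fr.values())
        if total <= 0 or total > 1 + 1e-9:
            raise ValueError("fractions must be positive and sum to <= 1")
        self.fractions = {k: v / total for k, v in fr.items()}
        if self.fitc_pos_log_mean - self.fitc_neg_log_mean < 1.0:
            raise ValueError("GFP+ and GFP- FITC medians must be >= 1 log10 unit apart")
        if not (0.0 <= self.gfp_loss_rate < 1.0):
            raise ValueError("gfp_loss_rate must be in [0, 1)")


# log10-scale location/scale of the non-FITC channels, per event class
_CHANNEL_PARAMS = {
    "fsc_h_live": (2.7, 0.08),
    "ssc_live": (2.5, 0.10),
    "dapi_live": (1.5, 0.20),
    "dapi_dead": (3.3, 0.15),
    "fsc_h_debris": (1.2, 0.25),
    "ssc_debris": (1.0, 0.30),
    "pe_pos": (2.3, 0.20),
    "pe_neg": (0.8, 0.30),
}


def simulate_flow_events(config: FlowSimConfig) -> pd.DataFrame:
    """Draw one sample's events from the mixture; truth labels retained.

    Columns: FSC_A, FSC_H, SSC, DAPI, FITC, PE (linear arbitrary units) and
    ``label`` in {gfp_pos, gfp_pos_lost, gfp_neg, dead, doublet, debris}.
    Doublets have FSC_A ~ 2x FSC_H (pulse area grows faster than height);
    dead cells take up DAPI and light up the 450/50 channel; debris sits at
    low scatter. Rows are shuffled so class order carries no information.
    """
    rng = np.random.default_rng(config.seed)
    classes = ["gfp_pos", "gfp_neg", "dead", "doublet", "debris"]
    probs = np.array([config.fractions[c] for c in classes])
    counts = rng.multinomial(config.n_events, probs)
    blocks = []

    def log10norm(mu, sd, n):
        return 10.0 ** rng.normal(mu, sd, n)

    def live_scatter(n, ratio_mu=1.05, ratio_sd=0.06):
        fsc_h = log10norm(*_CHANNEL_PARAMS["fsc_h_live"], n)
        fsc_a = fsc_h * rng.normal(ratio_mu, ratio_sd, n)
        ssc = log10norm(*_CHANNEL_PARAMS["ssc_live"], n)
        return fsc_a, fsc_h, ssc

    def fitc(kind, n):
        if kind == "pos":
            return log10norm(config.fitc_pos_log_mean, config.fitc_pos_log_sd, n)
        return log10norm(config.fitc_neg_log_mean, config.fitc_neg_log_sd, n)

    n_pos, n_neg, n_dead, n_dbl, n_deb = counts
    n_lost = rng.binomial(n_pos, config.gfp_loss_rate) if n_pos else 0
    n_pos_bright = n_pos - n_lost

    for label, n, fitc_kind in (
        ("gfp_pos", n_pos_bright, "pos"),
        ("gfp_pos_lost", n_lost, "neg"),
        ("gfp_neg", n_neg, "neg"),
    ):
        if n == 0:
            continue
        fsc_a, fsc_h, ssc = live_scatter(n)
        pe_kind = "pe_pos" if fitc_kind == "pos" else "pe_neg"
        blocks.append(
            pd.DataFrame(
                {
                    "FSC_A": fsc_a,
                    "FSC_H": fsc_h,
                    "SSC": ssc,
                    "DAPI": log10norm(*_CHANNEL_PARAMS["dapi_live"], n),
                    "FITC": fitc(fitc_kind, n),
                    "PE": log10norm(*_CHANNEL_PARAMS[pe_kind], n),
                    "label": label,
                }
            )
        )
    if n_dead:
        fsc_a, fsc_h, ssc = live_scatter(n_dead)
        blocks.append(
            pd.DataFrame(
                {
                    "FSC_A": fsc_a,
                    "FSC_H": fsc_h,
                    "SSC": ssc,
                    "DAPI": log10norm(*_CHANNEL_PARAMS["dapi_dead"], n_dead),
                    "FITC": fitc("neg", n_dead),
                    "PE": log10norm(*_CHANNEL_PARAMS["pe_neg"], n_dead),
                    "label": "dead",
                }
            )
        )
    if n_dbl:
        fsc_a, fsc_h, ssc = live_scatter(n_dbl, ratio_mu=1.95, ratio_sd=0.12)
        blocks.append(
            pd.DataFrame(
                {
                    "FSC_A": fsc_a,
                    "FSC_H": fsc_h,
                    "SSC": ssc,
                    "DAPI": log10norm(*_CHANNEL_PARAMS["dapi_live"], n_dbl),
                    "FITC": fitc("neg", n_dbl),
                    "PE": log10norm(*_CHANNEL_PARAMS["pe_neg"], n_dbl),
                    "label": "doublet",
                }
            )
        )
    if n_deb:
        fsc_h = log10norm(*_CHANNEL_PARAMS["fsc_h_debris"], n_deb)
        blocks.append(
            pd.DataFrame(
                {
                    "FSC_A": fsc_h * rng.normal(1.05, 0.10, n_deb),
                    "FSC_H": fsc_h,
                    "SSC": log10norm(*_CHANNEL_PARAMS["ssc_debris"], n_deb),
                    "DAPI": log10norm(*_CHANNEL_PARAMS["dapi_live"], n_deb),
                    "FITC": fitc("neg", n_deb),
                    "PE": log10norm(*_CHANNEL_PARAMS["pe_neg"], n_deb),
                    "label": "debris",
                }
            )
        )
    events = pd.concat(blocks, ignore_index=True)
    return events.iloc[rng.permutation(len(events))].reset_index(drop=True)


def competition_fractions(
    rho: float,
    generations: float,
    dead: float = 0.02,
    doublet: float = 0.02,
    debris: float = 0.02,
) -> dict:
    """Event-class fractions after a 1:1 co-culture grows ``generations``.

    A mutant with relative growth rate ``rho`` achieves rho*generations
    doublings while the GFP+ reference achieves ``generations``; starting
    from equal cell numbers, the mutant's share of live singlets is
    2**(rho*g) / (2**(rho*g) + 2**g). The expected normalized mutant
    fraction is therefore 1 / (1 + 2**((1-rho)*g)), which is the closed
    form end-to-end gating + classification should recover.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    live = 1.0 - dead - doublet - debris
    share = 2.0 ** (rho * generations)
    share = share / (share + 2.0**generations)
    return {
        "gfp_neg": live * share,
        "gfp_pos": live * (1.0 - share),
        "dead": dead,
        "doublet": doublet,
        "debris": debris,
    }
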