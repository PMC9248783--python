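"""Synthetic sequences and melt plates with planted, known truth.

Everything the pipeline consumes can be generated here: COI-like template
sets with planted species/haplotype structure, and raw melt-fluorescence
plates simulated from a two-state thermodynamic melt model.  Truth tables
accompany every output, so classification, clustering and haplotype
recovery can be scored exactly.

The melt model
--------------
A two-state (helix/coil) transition with logistic helicity

    theta(T) = 1 / (1 + exp((T - Tm) / s))

and observed fluorescence

    F(T) = (b0 + b1*T) + A * theta(T) + eps,   eps ~ N(0, sigma^2)

drawn independently per well and temperature.  -dF/dT then peaks exactly at
Tm (width controlled by s), which is what makes planted Tm values
recoverable by the processing chain.  This is a deliberately minimal model:
it exercises every pipeline contract but is NOT a physical prediction of
real multi-domain amplicon melts.

Amplicon Tm follows the salt-adjusted empirical GC/length rule

    Tm = 81.5 + 16.6*log10([Na+]) + 0.41*GC% - 600/N

fixed as this simulator's definition of melting temperature.  Under it,
GC-neutral substitutions (A<->T, G<->C) leave Tm exactly unchanged - the
mechanism by which distinct haplotypes can be indistinguishable by melt
curve, as in the three melt groups formed by the eight *Allolobophora
chlorotica* haplotypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .insilico import IUPAC, DegeneratePrimer
from .meltio import MeltDataset, SampleSeries, write_melt_table, write_sample_sheet
from .primers import COI_PAIR_LENGTHS, MULTIPLEX_PAIRS, PRIMERS

__all__ = [
    "SeqSimConfig",
    "MeltModelParams",
    "DEFAULT_GRID",
    "simulate_sequences",
    "amplicon_tm",
    "simulate_melt_plate",
    "multisite_template",
    "multiplex_templates",
    "make_fixture",
    "SCENARIOS",
]

#: The instrument ramp emulated throughout: 65 to 95 degC in 0.1 degC steps.
DEFAULT_GRID = np.linspace(65.0, 95.0, 301)

#: Noise gain of the default processing chain: white raw-RFU noise of SD
#: sigma passed through Savitzky-Golay (window 7, order 2) smoothing and
#: central differencing on the 0.1 degC grid emerges on -dF/dT with SD
#: ~= 3.25*sigma (root of the summed squared coefficients of the combined
#: linear filter).  Scenario fixtures state their plate conditions as
#: curve-level noise and divide by this gain to set the raw noise.
DERIVATIVE_NOISE_GAIN = 3.25

#: Curve-level noise SD (RFU/degC) planted by the scenario fixtures.
FIXTURE_CURVE_NOISE_SD = 0.01

EIGHT_SPECIES = [
    "Allolobophora_chlorotica",
    "Aporrectodea_caliginosa",
    "Aporrectodea_limicola",
    "Aporrectodea_longa",
    "Aporrectodea_rosea",
    "Lumbricus_castaneus",
    "Lumbricus_rubellus",
    "Lumbricus_terrestris",
]

SCENARIOS = ("eight_species", "caliginosa_longa_ambiguity", "chlorotica_haplotypes")


@dataclass
class SeqSimConfig:
    """Parameters of the planted-structure sequence simulator.

    The default core length (115 bp) plus the EW_COI_F2 (23 bp) and
    EW_COI_R1 (20 bp) footprints gives the assay's 158 bp product.
    """

    n_species: int = 8
    amplicon_core_length: int = 115
    n_haplotypes_per_species: int = 1
    substitutions_per_haplotype: int = 2
    gc_target: float = 0.4
    gc_neutral_fraction: float = 0.5
    flank_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "amplicon_core_length", "n_haplotypes_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.substitutions_per_haplotype > self.amplicon_core_length:
            raise ValueError("more substitutions requested than core positions")


@dataclass
class MeltModelParams:
    """Two-state melt simulation parameters.

    tm (degC) may be None when per-amplicon Tms are supplied; s is the
    transition width (degC), b0/b1 the linear baseline (RFU, RFU/degC),
    A the transition amplitude (RFU), noise_sd the per-point Gaussian
    measurement noise (RFU), na_molar the monovalent salt (mol/L).
    """

    tm: float | None = None
    s: float = 0.6
    b0: float = 1.0
    b1: float = -0.005
    A: float = 1.0
    noise_sd: float = 0.01
    na_molar: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("transition width s must be > 0")
        if self.A <= 0:
            raise ValueError("amplitude A must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.na_molar <= 0:
            raise ValueError("na_molar must be > 0")


def amplicon_tm(seq: str, na_molar: float = 0.05) -> float:
    """Salt-adjusted empirical Tm of a duplex (degC).

    Tm = 81.5 + 16.6*log10([Na+]) + 0.41*GC% - 600/N with GC% in percent
    and N the sequence length.  Bases other than A/C/G/T are tolerated up
    to a fraction of 0.1 and excluded from the GC count.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 20:
        raise ValueError("amplicon_tm needs a sequence of length >= 20")
    if na_molar <= 0:
        raise ValueError("na_molar must be > 0")
    ambiguous = sum(1 for b in seq if b not in "ACGT")
    if ambiguous / n > 0.1:
        raise ValueError(f"{ambiguous}/{n} ambiguous bases exceeds the 0.1 tolerance")
    gc = sum(1 for b in seq if b in "GC")
    gc_pct = 100.0 * gc / (n - ambiguous)
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * gc_pct - 600.0 / n


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choice(list("ATGC"), size=length, p=p))


def _dna_with_gc_count(rng: np.random.Generator, length: int, gc_count: int) -> str:
    """Random sequence with an exact number of G/C bases."""
    if not 0 <= gc_count <= length:
        raise ValueError("gc_count outside [0, length]")
    bases = [str(rng.choice(["G", "C"])) for _ in range(gc_count)]
    bases += [str(rng.choice(["A", "T"])) for _ in range(length - gc_count)]
    rng.shuffle(bases)
    return "".join(bases)


def _expand_one(rng: np.random.Generator, primer: DegeneratePrimer) -> str:
    """One concrete expansion of a degenerate primer, drawn uniformly."""
    return "".join(str(rng.choice(sorted(IUPAC[b]))) for b in primer.sequence)


_NEUTRAL_SWAP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_GC_FLIP = {"A": "G", "T": "C", "G": "A", "C": "T"}


def _substitute(core: str, positions: Sequence[int], neutral: Sequence[bool]) -> str:
    out = list(core)
    for pos, is_neutral in zip(positions, neutral):
        out[pos] = _NEUTRAL_SWAP[out[pos]] if is_neutral else _GC_FLIP[out[pos]]
    return "".join(out)


def simulate_sequences(cfg: SeqSimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Planted species/haplotype template set for the default primer pair.

    Each species gets a random core at the GC target, flanked by one
    concrete expansion of EW_COI_F2 and the reverse complement of one
    expansion of EW_COI_R1, plus random flanks - so every template yields
    exactly one 158 bp (by default) product.  Haplotypes within a species
    differ by the configured number of substitutions; a configurable
    fraction of those are GC-neutral and therefore leave the model Tm
    unchanged.  Returns (label -> template, truth table).
    """
    rng = np.random.default_rng(cfg.seed)
    fwd, rev = PRIMERS["EW_COI_F2"], PRIMERS["EW_COI_R1"]
    seqs: dict[str, str] = {}
    rows = []
    for si in range(cfg.n_species):
        species = f"sp{si + 1}"
        fwd_site = _expand_one(rng, fwd)
        rev_site = reverse_complement(_expand_one(rng, rev))
        base_core = _random_dna(rng, cfg.amplicon_core_length, cfg.gc_target)
        seen = {base_core}
        for hi in range(cfg.n_haplotypes_per_species):
            if hi == 0:
                core, positions, neutral = base_core, [], []
            else:
                for _ in range(200):  # retry until the haplotype core is novel
                    positions = sorted(rng.choice(cfg.amplicon_core_length,
                                                  size=cfg.substitutions_per_haplotype,
                                                  replace=False).tolist())
                    neutral = (rng.random(cfg.substitutions_per_haplotype)
                               < cfg.gc_neutral_fraction).tolist()
                    core = _substitute(base_core, positions, neutral)
                    if core not in seen:
                        break
                else:
                    raise RuntimeError("could not generate a novel haplotype core")
                seen.add(core)
            label = species if cfg.n_haplotypes_per_species == 1 else f"{species}_h{hi + 1}"
            left = _random_dna(rng, cfg.flank_length, cfg.gc_target)
            right = _random_dna(rng, cfg.flank_length, cfg.gc_target)
            seqs[label] = left + fwd_site + core + rev_site + right
            rows.append({
                "seq_id": label, "species": species, "haplotype": f"h{hi + 1}",
                "substitutions": ";".join(map(str, positions)),
                "gc_neutral": ";".join("1" if x else "0" for x in neutral),
                "core": core,
            })
    return seqs, pd.DataFrame(rows)


def simulate_melt_plate(amplicons: Mapping[str, str] | Mapping[str, float],
                        params: MeltModelParams,
                        replicates: int = 5,
                        grid: np.ndarray | None = None) -> tuple[MeltDataset, pd.DataFrame]:
    """Simulate a raw melt plate from amplicon sequences or explicit Tms.

    ``amplicons`` maps label -> DNA sequence (Tm computed by
    :func:`amplicon_tm`) or label -> Tm (degC).  Each label gets
    ``replicates`` wells named ``<label>_r<i>``; fluorescence follows the
    module's two-state model with independent Gaussian noise per well and
    temperature.  Returns (dataset, truth table well -> label/Tm/replicate).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    rng = np.random.default_rng(params.seed)
    samples: list[SampleSeries] = []
    rows = []
    for label, value in amplicons.items():
        tm = float(value) if isinstance(value, (int, float)) else amplicon_tm(str(value), params.na_molar)
        if tm < grid[0] or tm > grid[-1]:
            warnings.warn(
                f"label {label!r}: Tm {tm:.2f} outside the grid "
                f"[{grid[0]}, {grid[-1]}]; curve may have no interior peak",
                stacklevel=2,
            )
        theta = 1.0 / (1.0 + np.exp((grid - tm) / params.s))
        clean = params.b0 + params.b1 * grid + params.A * theta
        for r in range(1, replicates + 1):
            well = f"{label}_r{r}"
            noise = rng.normal(0.0, params.noise_sd, size=grid.size) if params.noise_sd > 0 else 0.0
            samples.append(SampleSeries(
                sample_id=well, rfu=clean + noise,
                label=label, replicate_group=label, role="reference",
            ))
            rows.append({"well": well, "label": label, "tm": tm, "replicate": r})
    dataset = MeltDataset(grid, samples, meta={
        "model": "two-state logistic", "s": params.s, "noise_sd": params.noise_sd,
        "na_molar": params.na_molar, "seed": params.seed,
    })
    return dataset, pd.DataFrame(rows)


def multisite_template(seed: int = 0, flank: int = 30, gc: float = 0.4) -> str:
    """A template carrying one concrete site for all six COI primers.

    Site offsets are derived from the published product-length table, so
    in-silico PCR on this template reproduces all nine pair lengths (and
    hence their offset-additivity structure).  The random fill is checked
    to introduce no spurious binding sites; the fill seed is advanced
    deterministically until the template is clean.
    """
    from .insilico import predict_amplicon  # local import avoids cycle at module load

    L = COI_PAIR_LENGTHS
    fwd_names = ["EW_COI_F1", "EW_COI_F2", "EW_COI_F3"]
    rev_names = ["EW_COI_R1", "EW_COI_R2", "EW_COI_R3"]
    # anchor the furthest-upstream forward site at `flank`
    base = max(L[(f, "EW_COI_R1")] for f in fwd_names)
    fwd_start = {f: flank + base - L[(f, "EW_COI_R1")] for f in fwd_names}
    rev_end = {r: fwd_start["EW_COI_F2"] + L[("EW_COI_F2", r)] for r in rev_names}
    total = max(rev_end.values()) + flank

    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        template = list(_random_dna(rng, total, gc))
        for f in fwd_names:
            site = _expand_one(rng, PRIMERS[f])
            start = fwd_start[f]
            template[start:start + len(site)] = site
        for r in rev_names:
            site = reverse_complement(_expand_one(rng, PRIMERS[r]))
            end = rev_end[r]
            template[end - len(site):end] = site
        text = "".join(template)
        ok = all(
            len(predict_amplicon(text, PRIMERS[f], PRIMERS[r], max_product=1000)) == 1
            for f in fwd_names for r in rev_names
        )
        if ok:
            return text
    raise RuntimeError("could not build a clean multi-site template")


def multiplex_templates(seed: int = 0, flank: int = 25) -> dict[str, str]:
    """Species-diagnostic multiplex templates.

    A 16S-like template for *Apo. caliginosa* carrying only the
    16S-Ac-F1 / WORM-16S-R1 sites (116 bp product) and a COI-like template
    for *Apo. longa* carrying only the COI-Al-F2 / COI-Al-R2 sites (213 bp
    product).  GC contents differ so the two products melt in disjoint Tm
    windows.
    """
    from .insilico import predict_amplicon

    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    specs = {
        "Aporrectodea_caliginosa": ("16S_caliginosa", 0.55),
        "Aporrectodea_longa": ("COI_longa", 0.35),
    }
    for species, (pair_key, gc) in specs.items():
        info = MULTIPLEX_PAIRS[pair_key]
        fwd, rev = PRIMERS[info["fwd"]], PRIMERS[info["rev"]]
        inner = info["length"] - len(fwd) - len(rev)
        for attempt in range(100):
            core = _dna_with_gc_count(rng, inner, round(gc * inner))
            left = _random_dna(rng, flank, 0.4)
            right = _random_dna(rng, flank, 0.4)
            template = left + fwd.sequence + core + reverse_complement(rev.sequence) + right
            hits = predict_amplicon(template, fwd, rev)
            cross = []
            for other_key, other in MULTIPLEX_PAIRS.items():
                if other_key != pair_key:
                    cross = predict_amplicon(template, PRIMERS[other["fwd"]],
                                             PRIMERS[other["rev"]])
            if len(hits) == 1 and hits[0].length == info["length"] and not cross:
                out[species] = template
                break
        else:
            raise RuntimeError(f"could not build a clean multiplex template for {species}")
    return out


def default_multiplex_rule(na_molar: float = 0.05,
                           half_width: float = 0.5) -> dict[str, tuple[float, float]]:
    """Tm windows for the multiplex assay, derived from simulated products.

    The windows are centred on the model Tms of the two diagnostic products
    (computed from the packaged multiplex templates at the default salt)
    and are configuration data, not measured biology; override them from a
    YAML rule file when calibrated product Tms are available.
    """
    from .insilico import predict_amplicon

    templates = multiplex_templates(seed=0)
    rule: dict[str, tuple[float, float]] = {}
    for species, template in templates.items():
        pair_key = "16S_caliginosa" if "caliginosa" in species else "COI_longa"
        info = MULTIPLEX_PAIRS[pair_key]
        amp = predict_amplicon(template, PRIMERS[info["fwd"]], PRIMERS[info["rev"]])[0]
        tm = amplicon_tm(amp.sequence, na_molar)
        rule[species] = (tm - half_width, tm + half_width)
    return rule


# ---------------------------------------------------------------------------
# scenario fixtures


def _eight_species_amplicons(rng: np.random.Generator) -> tuple[dict[str, str], dict[str, str]]:
    """Templates and amplicons for 8 species with Tm spacing >= 0.5 degC.

    Core GC counts step by 2 per species; with a 158 bp product each step
    moves the model Tm by 0.41 * 200/158 ~ 0.52 degC.  The primer-footprint
    sequence is shared across species, as in a real plate where the primers
    themselves write those bases into every amplicon.
    """
    fwd, rev = PRIMERS["EW_COI_F2"], PRIMERS["EW_COI_R1"]
    fwd_site = _expand_one(rng, fwd)
    rev_site = reverse_complement(_expand_one(rng, rev))
    templates: dict[str, str] = {}
    amplicons: dict[str, str] = {}
    core_len = 158 - len(fwd) - len(rev)  # 115
    for i, species in enumerate(EIGHT_SPECIES):
        core = _dna_with_gc_count(rng, core_len, 39 + 2 * i)
        left, right = _random_dna(rng, 30, 0.4), _random_dna(rng, 30, 0.4)
        templates[species] = left + fwd_site + core + rev_site + right
        amplicons[species] = fwd_site + core + rev_site
    return templates, amplicons


_CHLOROTICA_GROUPS = {"h1": 1, "h2": 2, "h3": 2, "h6": 2, "h7": 2,
                      "h4": 3, "h5": 3, "h8": 3}
_CHLOROTICA_COUNTS = {"h1": 4, "h2": 4, "h3": 3, "h4": 4, "h5": 3,
                      "h6": 4, "h7": 3, "h8": 3}  # 28 individuals


def _chlorotica_haplotype_cores(rng: np.random.Generator, core_len: int = 115) -> dict[str, str]:
    """Eight haplotype cores collapsing into three Tm groups.

    Group 2 haplotypes share two GC-raising substitutions (+2 GC -> +0.52
    degC); group 3 share four (+4 GC -> +1.04 degC).  Within a group the
    haplotypes differ only by GC-neutral swaps, so their model Tms are
    exactly equal: distinct sequences, indistinguishable melt curves.
    """
    base = _dna_with_gc_count(rng, core_len, 46)
    # GC-raising substitutions must sit on A/T bases (A->G, T->C adds one
    # GC each); neutral swaps may sit anywhere
    at_positions = [i for i, b in enumerate(base) if b in "AT"]
    pos = rng.choice(at_positions, size=9, replace=False).tolist()
    g2 = _substitute(base, pos[0:2], [False, False])
    g3 = _substitute(base, pos[0:4], [False] * 4)
    cores = {
        "h1": base,
        "h2": g2,
        "h3": _substitute(g2, [pos[4]], [True]),
        "h6": _substitute(g2, [pos[5]], [True]),
        "h7": _substitute(g2, [pos[6]], [True]),
        "h4": g3,
        "h5": _substitute(g3, [pos[7]], [True]),
        "h8": _substitute(g3, [pos[8]], [True]),
    }
    assert len(set(cores.values())) == 8
    return cores


def make_fixture(scenario: str, seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Build a named end-to-end test scenario, optionally writing it to disk.

    Scenarios:

    ``eight_species``
        8 species, Tms ~0.52 degC apart, 5 technical replicates each.
    ``caliginosa_longa_ambiguity``
        Two species whose 158 bp products have identical GC (Tm gap 0), so
        HRM cannot separate them; plus multiplex wells whose product Tms
        fall in disjoint windows, resolving the pair.
    ``chlorotica_haplotypes``
        28 individuals carrying 8 haplotypes that collapse into 3 melt
        groups (group 1: h1; group 2: h2, h3, h6, h7; group 3: h4, h5, h8).

    Returns a dict with the in-memory objects (dataset, truth, templates,
    ...); when ``out_dir`` is given, also writes melt.csv, samples.csv,
    seqs.fasta and truth.tsv there and records the paths.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(seed)
    raw_sd = FIXTURE_CURVE_NOISE_SD / DERIVATIVE_NOISE_GAIN
    params = MeltModelParams(noise_sd=raw_sd, seed=int(rng.integers(2**31)))

    if scenario == "eight_species":
        templates, amplicons = _eight_species_amplicons(rng)
        dataset, truth = simulate_melt_plate(amplicons, params, replicates=5)
        result = {"dataset": dataset, "truth": truth, "templates": templates,
                  "amplicons": amplicons}

    elif scenario == "caliginosa_longa_ambiguity":
        fwd, rev = PRIMERS["EW_COI_F2"], PRIMERS["EW_COI_R1"]
        fwd_site = _expand_one(rng, fwd)
        rev_site = reverse_complement(_expand_one(rng, rev))
        core_len = 158 - len(fwd) - len(rev)
        base = _dna_with_gc_count(rng, core_len, 46)
        # same GC count, different sequence: Tm gap exactly zero
        pos = rng.choice(core_len, size=3, replace=False).tolist()
        other = _substitute(base, pos, [True, True, True])
        amplicons = {
            "Aporrectodea_caliginosa": fwd_site + base + rev_site,
            "Aporrectodea_longa": fwd_site + other + rev_site,
        }
        dataset, truth = simulate_melt_plate(amplicons, params, replicates=5)
        # unknowns: one individual of each species, plus their multiplex wells
        mx_templates = multiplex_templates(seed=seed)
        rule = default_multiplex_rule(params.na_molar)
        unknown_truth = {"unknown1": "Aporrectodea_caliginosa",
                         "unknown2": "Aporrectodea_longa"}
        unknown_amps = {u: amplicons[sp] for u, sp in unknown_truth.items()}
        u_params = MeltModelParams(noise_sd=params.noise_sd, seed=int(rng.integers(2**31)))
        unknown_ds, _ = simulate_melt_plate(unknown_amps, u_params, replicates=1)
        mx_products = {}
        for u, sp in unknown_truth.items():
            pair_key = "16S_caliginosa" if "caliginosa" in sp else "COI_longa"
            info = MULTIPLEX_PAIRS[pair_key]
            from .insilico import predict_amplicon
            amp = predict_amplicon(mx_templates[sp], PRIMERS[info["fwd"]],
                                   PRIMERS[info["rev"]])[0]
            mx_products[f"{u}_mx"] = amp.sequence
        mx_params = MeltModelParams(noise_sd=params.noise_sd, seed=int(rng.integers(2**31)))
        mx_ds, _ = simulate_melt_plate(mx_products, mx_params, replicates=1)
        result = {"dataset": dataset, "truth": truth, "amplicons": amplicons,
                  "unknown_dataset": unknown_ds, "unknown_truth": unknown_truth,
                  "multiplex_dataset": mx_ds, "multiplex_rule": rule,
                  "multiplex_templates": mx_templates}

    else:  # chlorotica_haplotypes
        fwd, rev = PRIMERS["EW_COI_F2"], PRIMERS["EW_COI_R1"]
        fwd_site = _expand_one(rng, fwd)
        rev_site = reverse_complement(_expand_one(rng, rev))
        cores = _chlorotica_haplotype_cores(rng)
        templates: dict[str, str] = {}
        amplicons: dict[str, float] = {}
        truth_rows = []
        idx = 0
        for hap, count in _CHLOROTICA_COUNTS.items():
            amp_seq = fwd_site + cores[hap] + rev_site
            tm = amplicon_tm(amp_seq, params.na_molar)
            for _ in range(count):
                idx += 1
                ind = f"chl{idx:02d}"
                left, right = _random_dna(rng, 30, 0.4), _random_dna(rng, 30, 0.4)
                templates[ind] = left + fwd_site + cores[hap] + rev_site + right
                amplicons[ind] = tm
                truth_rows.append({"well": f"{ind}_r1", "individual": ind,
                                   "haplotype": hap, "group": _CHLOROTICA_GROUPS[hap],
                                   "tm": tm})
        dataset, _ = simulate_melt_plate(amplicons, params, replicates=1)
        for s in dataset.samples:  # one well per individual, no replication
            s.label = None
            s.role = "unknown"
        result = {"dataset": dataset, "truth": pd.DataFrame(truth_rows),
                  "templates": templates,
                  "haplotype_groups": dict(_CHLOROTICA_GROUPS)}

    if out_dir is not None:
        result["paths"] = _write_fixture(scenario, result, Path(out_dir))
    return result


def _write_fixture(scenario: str, result: dict, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ds: MeltDataset = result["dataset"]
    paths["melt"] = out_dir / "melt.csv"
    write_melt_table(ds, paths["melt"], header_lines=[f"scenario: {scenario}"])
    paths["samples"] = out_dir / "samples.csv"
    write_sample_sheet(ds, paths["samples"])
    truth = result["truth"]
    paths["truth"] = out_dir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    templates = result.get("templates") or result.get("amplicons")
    if isinstance(templates, dict) and templates and isinstance(next(iter(templates.values())), str):
        paths["fasta"] = out_dir / "seqs.fasta"
        with paths["fasta"].open("w", encoding="utf-8") as fh:
            for label, seq in templates.items():
                fh.write(f">{label}\n{seq}\n")
    if "multiplex_rule" in result:
        import yaml

        paths["multiplex_rule"] = out_dir / "multiplex.yaml"
        with paths["multiplex_rule"].open("w", encoding="utf-8") as fh:
            yaml.safe_dump({k: [float(a), float(b)]
                            for k, (a, b) in result["multiplex_rule"].items()}, fh)
    return paths
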