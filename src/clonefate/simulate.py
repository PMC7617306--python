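"""Synthetic co-culture experiment generator with retained ground truth.

Emulates a DNA-barcode lineage-tracing experiment in which barcoded
leukaemic (B-ALL) cells are cultured for two sampling timepoints either
alone or together with NK cells, in replicate wells sequenced in technical
duplicate.  Clones are founded through a low-MOI transduction bottleneck
(each founder carries one random 21-nt barcode), receive a generating fate,
and their read counts follow a negative-binomial model around expected
frequencies shaped by per-fate log2 fold changes in the NK arm:

* ``eliminated``        — strong negative lfc in every NK well,
* ``primary_resistant`` — positive lfc in every NK well (intrinsic),
* ``static``            — lfc 0,
* ``secondary_resistant`` — resistance acquired stochastically in a single
  well: positive lfc in exactly one NK well (at the later timepoint only),
  the eliminated-class lfc elsewhere,
* ``other``             — no systematic effect (weight 0 by default).

NK selection pressure accumulates over time: effects are applied at half
strength at TP1 and full strength at TP2, so secondary expansion is a
late-timepoint phenomenon.  Raw reads are then synthesized per sample as
head-anchor + barcode + tail-anchor amplicons padded to the read length,
with a configurable fraction of defective reads (wrong insert length,
uncalled bases, missing anchors) mimicking the ~15% of sequences a real
run discards.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import CountMatrix, ALONE, NK, TP1, TP2
from .errors import ConfigurationError
from .extract import HEAD_ANCHOR, TAIL_ANCHOR, BARCODE_LENGTH
from .reference import BarcodeLibrary

FATES = ("eliminated", "primary_resistant", "static", "secondary_resistant", "other")

#: Per-category mean fractions of clone fates observed after two weeks of
#: NK co-culture (pooled over cell lines and experiments); used as the
#: generating fate distribution.
DEFAULT_FATE_WEIGHTS = {
    "eliminated": 0.585,
    "primary_resistant": 0.143,
    "static": 0.239,
    "secondary_resistant": 0.033,
    "other": 0.0,
}

#: Log2 fold changes applied in the NK arm at the later timepoint.
#: Elimination is modelled as near-complete clearance (-10 ~= 0.1% of the
#: untreated abundance, i.e. >99.9% killing after two weeks of co-culture);
#: primary resistance as a strong reproducible expansion; secondary
#: resistance as a one-well expansion on top of the eliminated-class
#: behaviour in the remaining wells.
DEFAULT_EFFECT_SIZES = {
    "eliminated": -10.0,
    "primary_resistant": 3.0,
    "static": 0.0,
    "secondary_resistant": 2.0,
    "other": 0.0,
}

DEFAULT_MALFORMED_MIX = {
    "short_insert": 0.2,
    "long_insert": 0.2,
    "uncalled_base": 0.2,
    "missing_head": 0.2,
    "missing_tail": 0.2,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic experiment."""

    n_clones: int = 3000
    barcode_length: int = BARCODE_LENGTH
    fate_weights: dict = field(default_factory=lambda: dict(DEFAULT_FATE_WEIGHTS))
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    founder_sigma: float = 0.5          # log-normal skew of founder abundances
    dispersion: float = 0.05            # NB overdispersion (var = m + a m^2)
    depth_per_barcode: float = 75.0     # mean reads per barcode per library
    malformed_fraction: float = 0.15
    malformed_mix: dict = field(default_factory=lambda: dict(DEFAULT_MALFORMED_MIX))
    n_wells: int = 3
    n_techreps: int = 2
    n_library_samples: int = 4
    read_length: int = 64
    head: str = HEAD_ANCHOR
    tail: str = TAIL_ANCHOR
    cell_line: str = "A"
    nk_genotype: str = "WT"
    timepoint_scale: dict = field(default_factory=lambda: {TP1: 0.5, TP2: 1.0})
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_clones < 0:
            raise ConfigurationError("n_clones must be >= 0")
        if self.barcode_length < 1:
            raise ConfigurationError("barcode_length must be >= 1")
        if set(self.fate_weights) != set(FATES):
            raise ConfigurationError(f"fate_weights must have keys {FATES}")
        w = np.array([self.fate_weights[f] for f in FATES], dtype=float)
        if (w < 0).any() or (w > 1).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("fate_weights must be probabilities summing to 1")
        m = np.array(list(self.malformed_mix.values()), dtype=float)
        if (m < 0).any() or abs(m.sum() - 1.0) > 1e-9:
            raise ConfigurationError("malformed_mix must be proportions summing to 1")
        if not 0.0 <= self.malformed_fraction < 1.0:
            raise ConfigurationError("malformed_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.depth_per_barcode <= 0:
            raise ConfigurationError("depth_per_barcode must be positive")
        if self.n_wells < 1 or self.n_techreps < 1 or self.n_library_samples < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if self.founder_sigma < 0:
            raise ConfigurationError("founder_sigma must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimulationTruth:
    """Per-clone generating fate and applied effect sizes.

    ``clones`` has one row per clone (barcode, fate, founder_abundance,
    expanded_well with -1 meaning not applicable); ``lfc_by_well`` holds
    the per-well log2 fold changes applied in the NK arm at the later
    timepoint, aligned with ``clones`` rows.
    """

    clones: pd.DataFrame
    lfc_by_well: np.ndarray

    @property
    def barcodes(self) -> pd.Index:
        return pd.Index(self.clones["barcode"])

    def validate(self) -> None:
        n = len(self.clones)
        if self.lfc_by_well.shape[0] != n:
            raise ConfigurationError("lfc_by_well misaligned with clone table")
        if self.clones["barcode"].duplicated().any():
            raise ConfigurationError("barcodes must be unique")
        if n and abs(self.clones["founder_abundance"].sum() - 1.0) > 1e-9:
            raise ConfigurationError("founder abundances must sum to 1")

    def to_tsv(self, path) -> None:
        out = self.clones.copy()
        for w in range(self.lfc_by_well.shape[1] if len(self.clones) else 0):
            out[f"lfc_well{w + 1}"] = self.lfc_by_well[:, w]
        out.to_csv(path, sep="\t", index=False)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng([config.seed, stream])


def _random_barcodes(rng, n: int, length: int) -> np.ndarray:
    """n unique random barcode strings over ACGT."""
    if n == 0:
        return np.array([], dtype=object)
    if length * np.log(4) < np.log(max(n, 1)) or 4 ** min(length, 40) < n:
        raise ConfigurationError(
            f"cannot draw {n} unique barcodes of length {length}")
    seen: dict[str, None] = {}
    while len(seen) < n:
        draw = _BASES[rng.integers(0, 4, size=(n - len(seen) + 8, length))]
        for row in draw.view(f"S{length}")[:, 0]:
            seen.setdefault(row.decode(), None)
            if len(seen) == n:
                break
    return np.array(list(seen), dtype=object)


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2
    (Poisson when dispersion == 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        size = 1.0 / dispersion
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def generate_library(config: GeneratorConfig) -> tuple[BarcodeLibrary, SimulationTruth]:
    """Draw the founder clone population and its viral-library sequencing.

    Returns the (unfiltered) reference library with simulated counts for
    ``n_library_samples`` library samples, and the per-clone ground truth.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config, 0)
    n = config.n_clones
    barcodes = _random_barcodes(rng, n, config.barcode_length)
    if n == 0:
        clones = pd.DataFrame(columns=["barcode", "fate", "founder_abundance",
                                       "expanded_well"])
        truth = SimulationTruth(clones, np.zeros((0, config.n_wells)))
        lib = BarcodeLibrary(pd.DataFrame(
            index=pd.Index([], name="barcode"),
            columns=[f"lib_{i + 1}" for i in range(config.n_library_samples)],
            dtype="int64"))
        return lib, truth

    founder = rng.lognormal(mean=0.0, sigma=config.founder_sigma, size=n)
    founder /= founder.sum()
    weights = np.array([config.fate_weights[f] for f in FATES])
    fates = rng.choice(len(FATES), size=n, p=weights)
    fate_labels = np.array(FATES, dtype=object)[fates]
    expanded = np.where(fate_labels == "secondary_resistant",
                        rng.integers(0, config.n_wells, size=n), -1)

    lfc = np.zeros((n, config.n_wells))
    for i, fate in enumerate(FATES):
        rows = fates == i
        if fate == "secondary_resistant":
            lfc[rows] = config.effect_sizes["eliminated"]
        else:
            lfc[rows] = config.effect_sizes[fate]
    sec = expanded >= 0
    lfc[np.nonzero(sec)[0], expanded[sec]] = config.effect_sizes["secondary_resistant"]

    clones = pd.DataFrame({
        "barcode": barcodes,
        "fate": fate_labels,
        "founder_abundance": founder,
        "expanded_well": expanded,
    })
    truth = SimulationTruth(clones, lfc)
    truth.validate()

    lib_mean = founder * n * config.depth_per_barcode
    lib_counts = {
        f"lib_{i + 1}": _nb_draw(rng, lib_mean, config.dispersion)
        for i in range(config.n_library_samples)
    }
    lib_table = pd.DataFrame(lib_counts, index=pd.Index(barcodes, name="barcode"))
    return BarcodeLibrary(lib_table.sort_index()), truth


def _tp_lfc(truth: SimulationTruth, config: GeneratorConfig, timepoint: str) -> np.ndarray:
    """Per-well lfc matrix at a timepoint; secondary expansion only at TP2."""
    lfc = truth.lfc_by_well.copy()
    if timepoint != TP2:
        sec = truth.clones["expanded_well"].to_numpy() >= 0
        rows = np.nonzero(sec)[0]
        lfc[rows, truth.clones["expanded_well"].to_numpy()[rows]] = \
            config.effect_sizes["eliminated"]
    return lfc


def expected_frequencies(truth: SimulationTruth, config: GeneratorConfig,
                         condition: str, timepoint: str, well: int) -> np.ndarray:
    """Expected clone frequencies in one well (renormalised in the NK arm)."""
    founder = truth.clones["founder_abundance"].to_numpy()
    if condition == ALONE:
        return founder.copy()
    scale = config.timepoint_scale[timepoint]
    with np.errstate(over="ignore"):
        raw = founder * np.exp2(_tp_lfc(truth, config, timepoint)[:, well] * scale)
    total = raw.sum()
    if total <= 0:
        return np.zeros_like(raw)
    return raw / total


def simulate_coculture(truth: SimulationTruth,
                       config: GeneratorConfig) -> CountMatrix:
    """Simulate the read counts of the full co-culture design.

    Two conditions x two timepoints x ``n_wells`` wells x ``n_techreps``
    technical replicates; counts per technical replicate are NB around
    frequency x n_clones x depth_per_barcode.  Deterministic given seed.
    """
    rng = _rng(config, 1)
    n = len(truth.clones)
    cols, meta = {}, []
    for timepoint in (TP1, TP2):
        for condition in (ALONE, NK):
            for well in range(config.n_wells):
                freq = expected_frequencies(truth, config, condition, timepoint, well)
                mean = freq * n * config.depth_per_barcode
                for rep in range(config.n_techreps):
                    sid = (f"{config.cell_line}_{condition}_{timepoint}"
                           f"_w{well + 1}_r{rep + 1}")
                    cols[sid] = _nb_draw(rng, mean, config.dispersion)
                    meta.append(dict(
                        sample_id=sid, cell_line=config.cell_line,
                        condition=condition,
                        nk_genotype=config.nk_genotype if condition == NK else "none",
                        timepoint=timepoint, well=well + 1, techrep=rep + 1))
    samples = pd.DataFrame(meta).set_index("sample_id")
    counts = pd.DataFrame(cols, index=pd.Index(truth.barcodes, name="barcode"))
    return CountMatrix(counts.sort_index(), samples)


def library_count_matrix(library: BarcodeLibrary,
                         config: GeneratorConfig) -> CountMatrix:
    """Wrap viral-library sample counts as a CountMatrix for read synthesis."""
    meta = pd.DataFrame([
        dict(sample_id=sid, cell_line=config.cell_line, condition="library",
             nk_genotype="none", timepoint="TP0", well=i + 1, techrep=1)
        for i, sid in enumerate(library.library_counts.columns)
    ]).set_index("sample_id")
    return CountMatrix(library.library_counts.copy(), meta)


# ---------------------------------------------------------------------------
# read synthesis

_DEFECTS = ("short_insert", "long_insert", "uncalled_base", "missing_head",
            "missing_tail")


def _assemble(rng, head: bytes, tail: bytes, inserts: np.ndarray,
              read_length: int) -> np.ndarray:
    """Stack head + insert + tail and right-pad with random bases."""
    n, ins_len = inserts.shape
    reads = np.empty((n, read_length), dtype=np.uint8)
    h, t = len(head), len(tail)
    reads[:, :h] = np.frombuffer(head, dtype=np.uint8)
    reads[:, h:h + ins_len] = inserts
    reads[:, h + ins_len:h + ins_len + t] = np.frombuffer(tail, dtype=np.uint8)
    pad = read_length - h - ins_len - t
    if pad > 0:
        reads[:, -pad:] = _BASES[rng.integers(0, 4, size=(n, pad))]
    return reads


def _malformed_reads(rng, config: GeneratorConfig, bc_rows: np.ndarray,
                     n_by_class: np.ndarray) -> np.ndarray:
    """Defective reads, one block per defect class; bc_rows are barcode
    byte-rows to corrupt (length = total malformed)."""
    head = config.head.encode()
    tail = config.tail.encode()
    L = config.read_length
    blocks = []
    start = 0
    for cls, m in zip(_DEFECTS, n_by_class):
        if m == 0:
            continue
        rows = bc_rows[start:start + m]
        start += m
        if cls == "short_insert":
            blocks.append(_assemble(rng, head, tail, rows[:, :-1], L))
        elif cls == "long_insert":
            extra = _BASES[rng.integers(0, 4, size=(m, 1))]
            blocks.append(_assemble(rng, head, tail,
                                    np.concatenate([rows, extra], axis=1), L))
        elif cls == "uncalled_base":
            corrupted = rows.copy()
            pos = rng.integers(0, rows.shape[1], size=m)
            corrupted[np.arange(m), pos] = ord("N")
            blocks.append(_assemble(rng, head, tail, corrupted, L))
        elif cls == "missing_head":
            fake = _BASES[rng.integers(0, 4, size=(m, len(head)))]
            reads = _assemble(rng, head, tail, rows, L)
            reads[:, :len(head)] = fake
            blocks.append(reads)
        elif cls == "missing_tail":
            reads = _assemble(rng, head, tail, rows, L)
            fill = _BASES[rng.integers(0, 4, size=(m, L - len(head) - rows.shape[1]))]
            reads[:, len(head) + rows.shape[1]:] = fill
            blocks.append(reads)
    if not blocks:
        return np.empty((0, L), dtype=np.uint8)
    return np.concatenate(blocks, axis=0)


def synthesize_reads(counts: CountMatrix, truth: SimulationTruth,
                     config: GeneratorConfig, outdir,
                     gzip_output: bool = False) -> dict[str, Path]:
    """Write one FASTQ file per sample.

    Every (barcode, sample) pair contributes exactly its count of intact
    reads (head + barcode + tail, padded with random bases to the read
    length, uniform high base quality).  Malformed reads are injected on
    top so their share of all reads matches ``malformed_fraction`` in
    expectation, split over defect classes by ``malformed_mix``.
    Deterministic given seed; the RNG seed is recorded in the first read
    header of each file.
    """
    min_len = len(config.head) + config.barcode_length + len(config.tail)
    if config.read_length < min_len:
        raise ConfigurationError(
            f"read_length {config.read_length} shorter than anchors + barcode "
            f"({min_len})")
    known = set(truth.barcodes)
    missing = [b for b in counts.barcodes if b not in known]
    if missing:
        raise ConfigurationError(
            f"{len(missing)} barcodes in counts absent from truth")

    rng = _rng(config, 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    barcodes = counts.barcodes
    bc_matrix = (np.frombuffer("".join(barcodes).encode(), dtype=np.uint8)
                 .reshape(len(barcodes), config.barcode_length)
                 if len(barcodes) else
                 np.empty((0, config.barcode_length), dtype=np.uint8))
    head, tail = config.head.encode(), config.tail.encode()
    mix = np.array([config.malformed_mix.get(c, 0.0) for c in _DEFECTS])
    qual = b"I" * config.read_length
    f = config.malformed_fraction
    paths: dict[str, Path] = {}

    for sid in counts.counts.columns:
        c = counts.counts[sid].to_numpy()
        total = int(c.sum())
        intact = _assemble(rng, head, tail,
                           bc_matrix[np.repeat(np.arange(len(c)), c)],
                           config.read_length)
        n_mal = int(rng.poisson(total * f / (1.0 - f))) if (f > 0 and total > 0) else 0
        if n_mal > 0:
            src = rng.choice(len(c), size=n_mal, p=c / total)
            per_class = rng.multinomial(n_mal, mix / mix.sum())
            malformed = _malformed_reads(rng, config, bc_matrix[src], per_class)
        else:
            malformed = np.empty((0, config.read_length), dtype=np.uint8)
        reads = np.concatenate([intact, malformed], axis=0)
        reads = reads[rng.permutation(reads.shape[0])]

        name = f"{sid}.fastq" + (".gz" if gzip_output else "")
        path = outdir / name
        opener = gzip.open if gzip_output else open
        with opener(path, "wb") as fh:
            seqs = reads.reshape(-1) .view(f"S{config.read_length}") \
                if reads.size else np.empty(0, dtype=f"S{config.read_length}")
            chunk: list[bytes] = []
            for i in range(reads.shape[0]):
                desc = b" seed=%d" % config.seed if i == 0 else b""
                chunk.append(b"@%s.%d%s\n%s\n+\n%s\n"
                             % (sid.encode(), i, desc, seqs[i], qual))
                if len(chunk) >= 100000:
                    fh.write(b"".join(chunk))
                    chunk = []
            fh.write(b"".join(chunk))
        paths[sid] = path
    return paths


@dataclass
class SimulatedExperiment:
    """File layout of one synthesized experiment."""

    config: GeneratorConfig
    truth: SimulationTruth
    library: BarcodeLibrary
    coculture_counts: CountMatrix
    fastq: dict[str, Path]
    library_fastq: dict[str, Path]
    outdir: Path


def simulate_experiment(config: GeneratorConfig, outdir) -> SimulatedExperiment:
    """Full generator: truth + library + counts + FASTQ files + sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library, truth = generate_library(config)
    coculture = simulate_coculture(truth, config)
    lib_cm = library_count_matrix(library, config)
    fastq_dir = outdir / "fastq"
    lib_paths = synthesize_reads(lib_cm, truth, config, fastq_dir)
    sample_paths = synthesize_reads(coculture, truth, config, fastq_dir)
    truth.to_tsv(outdir / "truth.tsv")
    coculture.samples.to_csv(outdir / "samples.tsv", sep="\t",
                             index_label="sample_id")
    config.to_yaml(outdir / "config.yaml")
    manifest = {sid: str(p) for sid, p in {**lib_paths, **sample_paths}.items()}
    (outdir / "fastq_manifest.json").write_text(json.dumps(manifest, indent=1))
    return SimulatedExperiment(config, truth, library, coculture,
                               sample_paths, lib_paths, outdir)


def genotype_config(base: GeneratorConfig, genotype: str) -> GeneratorConfig:
    """Scenario presets for NK effector genotypes.

    Perforin- or IFN-gamma-deficient NK cells kill less efficiently; the
    presets shrink the eliminated fate fraction (by 20% and 40%) and move
    the difference into the static pool, which reduces the diversity drop
    accordingly.  Schematic, not a fitted model.
    """
    scale = {"WT": 1.0, "Prf1KO": 0.8, "IfngKO": 0.6}
    if genotype not in scale:
        raise ConfigurationError(f"unknown genotype {genotype!r}")
    w = dict(base.fate_weights)
    delta = w["eliminated"] * (1.0 - scale[genotype])
    w["eliminated"] -= delta
    w["static"] += delta
    cfg = GeneratorConfig(**{**asdict(base), "fate_weights": w,
                             "nk_genotype": genotype})
    return cfg
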