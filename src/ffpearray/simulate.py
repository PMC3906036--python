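"""Synthetic transcriptome, chip design and matched frozen/FFPE intensities.

The generator emulates the situation the rest of the package is built for:
a 3'-biased expression array hybridized to matched fresh-frozen and
formalin-fixed (FFPE) aliquots of the same samples.  Ground truth (gene
expression, differential-expression status, probe affinities, per-sample
degradation scales) is returned alongside the data so recovery can be
checked exactly.

Signal model, on the log2 scale, for a matching probe ``p`` of gene ``g``
in sample (pair) ``j``::

    frozen:  I = 2^(g_gj + a_p + eps)              [+ optical background]
    FFPE:    I = 2^(g_gj + a_p + eps) * exp(-d_p / lambda_j)
                                                   [+ optical background]

where ``a_p`` is a per-probe affinity offset, ``eps`` Gaussian measurement
noise, ``d_p`` the probe's 3' distance and ``lambda_j`` a per-FFPE-sample
exponential decay scale in bp.  Fragmentation of archival RNA removes
probe targets in proportion to their distance from the 3' end, hence the
multiplicative exponential decay; the additive optical background term
(enabled by default) reproduces the floor that makes decayed probes
collapse toward noise — exactly the regime the normal+exponential RMA
background model assumes.

The chip design mirrors the pathologies of a dated vendor annotation: each
gene's vendor probeset also contains *stale* probes that no longer match
any transcript, a configurable number of probes is *ambiguous* (their
25-mer is planted into two transcripts), some probes match nothing at all,
and a fraction of genes is split across two vendor probesets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cdf import PROBE_LENGTH, Probe, ProbeHit, Transcript, map_probes
from .errors import ConfigurationError, ConsistencyError

LOG2E = float(np.log2(np.e))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model.

    Defaults describe a mid-sized benchmark: 2,000 genes, 10 matched pairs
    per molecular subgroup, a fixed FFPE decay scale of 150 bp, and noise
    twice as large on the FFPE arm as on the frozen arm.
    """

    n_genes: int = 2000
    transcript_length_range: tuple[int, int] = (800, 1600)
    probes_per_gene: int = 9
    probe_spacing: int = 50
    n_ambiguous_probes: int = 20
    n_background_probes: int = 50
    stale_probes_per_gene: int = 2
    frac_second_probeset: float = 0.3
    second_probeset_probes: int = 6
    n_samples_per_subgroup: int = 10
    frac_de_genes: float = 0.15
    de_effect_log2: float = 1.0
    base_expression_mean: float = 7.0
    base_expression_sd: float = 2.0
    biological_sd: float = 0.5
    probe_affinity_sd: float = 0.7
    noise_sd_frozen: float = 0.25
    noise_sd_ffpe: float = 0.5
    decay_scale_range: tuple[float, float] = (150.0, 150.0)
    background_log2: float = 4.0
    background_sd: float = 0.3
    additive_background: bool = True
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.transcript_length_range
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ConfigurationError("n_genes and probes_per_gene must be >= 1")
        if not (PROBE_LENGTH <= lo <= hi):
            raise ConfigurationError("transcript_length_range must be >= 25 and ordered")
        if self.probe_spacing < 1:
            raise ConfigurationError("probe_spacing must be >= 1")
        for name in ("n_ambiguous_probes", "n_background_probes", "stale_probes_per_gene"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if 2 * self.n_ambiguous_probes > self.n_genes:
            raise ConfigurationError("need at least two genes per ambiguous probe")
        for name in ("frac_de_genes", "frac_second_probeset"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in (
            "biological_sd",
            "probe_affinity_sd",
            "noise_sd_frozen",
            "noise_sd_ffpe",
            "background_sd",
            "base_expression_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        dlo, dhi = self.decay_scale_range
        if not (0 < dlo <= dhi):
            raise ConfigurationError("decay_scale_range must be positive and ordered")
        if self.n_samples_per_subgroup < 1:
            raise ConfigurationError("n_samples_per_subgroup must be >= 1")

    @property
    def max_tile_distance(self) -> int:
        n = self.probes_per_gene + self.second_probeset_probes
        return (n - 1) * self.probe_spacing


@dataclass
class ChipDesign:
    """Output of :func:`simulate_chip_design`.

    Transcripts are returned (possibly modified — ambiguous 25-mers are
    planted into acceptor transcripts) together with the probe list, true
    per-probe affinities and the identities of the planted pathologies.
    ``ambiguous_sites`` records every (gene, start) occurrence of each
    ambiguous probe so intensities can include both targets.
    """

    probes: list[Probe]
    transcripts: dict[str, Transcript]
    probe_affinity: pd.Series
    ambiguous_sites: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    background_probe_ids: set[str] = field(default_factory=set)
    stale_probe_ids: set[str] = field(default_factory=set)

    @property
    def matching_probe_ids(self) -> set[str]:
        special = (
            self.background_probe_ids | self.stale_probe_ids | set(self.ambiguous_sites)
        )
        return {p.probe_id for p in self.probes} - special


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not.

    ``gene_expression`` is the gene x pair log2 matrix shared by the two
    preservation arms of each matched pair; ``decay_scale`` the per-FFPE-
    sample lambda in bp.
    """

    gene_expression: pd.DataFrame
    de_gene_ids: set[str]
    de_sign: dict[str, int]
    probe_affinity: pd.Series
    decay_scale: pd.Series
    subgroup: pd.Series  # pair id -> subgroup label


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    transcripts: dict[str, Transcript]
    probes: list[Probe]
    design: ChipDesign
    hits: list[ProbeHit]
    truth: GroundTruth
    frozen: pd.DataFrame
    ffpe: pd.DataFrame
    annotation: pd.DataFrame


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # one substream per pipeline stage, all derived from the single seed
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), stage)))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def simulate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, Transcript]:
    """One random transcript per gene, lengths uniform in the configured range."""
    config.validate()
    rng = rng if rng is not None else _stage_rng(config.seed, 0)
    lo, hi = config.transcript_length_range
    transcripts: dict[str, Transcript] = {}
    for i in range(config.n_genes):
        gene = f"G{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        transcripts[gene] = Transcript(gene, f"T{i:05d}.1", _random_sequence(rng, length))
    return transcripts


def simulate_chip_design(
    transcripts: Mapping[str, Transcript],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ChipDesign:
    """Tile probes over each transcript and plant annotation pathologies.

    Per gene, ``probes_per_gene`` 25-mers are copied verbatim from the
    transcript at 3' distances ``0, s, 2s, ...`` (``s = probe_spacing``);
    the vendor probeset lists them 5'->3' after ``stale_probes_per_gene``
    random non-matching probes.  A fraction of genes receives a second
    vendor probeset tiling further 5'.  ``n_ambiguous_probes`` extra probes
    are made ambiguous by planting their 25-mer into a second transcript
    (both copies land in the free 5' region no tiled probe occupies).
    Transcripts too short for the full tiling get only the probes that fit
    (with a warning if none fit).
    """
    config.validate()
    if not transcripts:
        raise ConfigurationError("no transcripts supplied")
    rng = rng if rng is not None else _stage_rng(config.seed, 1)
    genes = sorted(transcripts)
    work = {g: transcripts[g].sequence for g in genes}

    # Ambiguity planting must precede tiling so tiled probes are verbatim
    # copies of the final transcript sequences.
    ambiguous_sites: dict[str, list[tuple[str, int]]] = {}
    ambiguous_records: list[tuple[str, str, str]] = []  # (probe_id, probeset, seq)
    plant_pos = 5
    for k in range(config.n_ambiguous_probes):
        donor, acceptor = genes[2 * k], genes[2 * k + 1]
        for g in (donor, acceptor):
            free = len(work[g]) - PROBE_LENGTH - config.max_tile_distance
            if free < plant_pos + PROBE_LENGTH:
                raise ConfigurationError(
                    f"transcript {g} too short to plant an ambiguous probe"
                )
        seq = work[donor][plant_pos : plant_pos + PROBE_LENGTH]
        work[acceptor] = (
            work[acceptor][:plant_pos] + seq + work[acceptor][plant_pos + PROBE_LENGTH :]
        )
        pid = f"AMB{k:03d}"
        ambiguous_records.append((pid, f"AMB{k:03d}_at", seq))
        ambiguous_sites[pid] = [(donor, plant_pos), (acceptor, plant_pos)]

    final_transcripts = {
        g: replace(transcripts[g], sequence=work[g]) for g in genes
    }

    probes: list[Probe] = []
    stale_ids: set[str] = set()
    n_second = int(round(config.frac_second_probeset * len(genes)))
    second_idx = set(
        rng.choice(len(genes), size=n_second, replace=False) if n_second else []
    )

    def tile(gene: str, start_k: int, count: int) -> list[Probe]:
        seq = work[gene]
        out = []
        for k in range(start_k, start_k + count):
            d = k * config.probe_spacing
            s = len(seq) - PROBE_LENGTH - d
            if s < 0:
                break
            out.append(
                Probe(
                    f"{gene}_p{k:02d}",
                    f"{gene}_at" if k < config.probes_per_gene else f"{gene}_s_at",
                    seq[s : s + PROBE_LENGTH],
                )
            )
        return out

    for gi, gene in enumerate(genes):
        main = tile(gene, 0, config.probes_per_gene)
        if not main:
            warnings.warn(f"transcript {gene} shorter than one probe tile; skipped")
            continue
        # stale probes first (5' side of the listing), then matches 5'->3'
        for s in range(config.stale_probes_per_gene):
            pid = f"{gene}_x{s}"
            probes.append(Probe(pid, f"{gene}_at", _random_sequence(rng, PROBE_LENGTH)))
            stale_ids.add(pid)
        probes.extend(reversed(main))  # decreasing distance = 5'->3'
        if gi in second_idx:
            extra = tile(gene, config.probes_per_gene, config.second_probeset_probes)
            probes.extend(reversed(extra))

    for pid, ps, seq in ambiguous_records:
        probes.append(Probe(pid, ps, seq))

    background_ids: set[str] = set()
    for b in range(config.n_background_probes):
        pid = f"BG{b:03d}"
        probes.append(Probe(pid, f"BG{b // 11:02d}_at", _random_sequence(rng, PROBE_LENGTH)))
        background_ids.add(pid)

    affinity = pd.Series(
        rng.normal(0.0, config.probe_affinity_sd, size=len(probes)),
        index=[p.probe_id for p in probes],
        name="probe_affinity",
    )
    return ChipDesign(
        probes=probes,
        transcripts=final_transcripts,
        probe_affinity=affinity,
        ambiguous_sites=ambiguous_sites,
        background_probe_ids=background_ids,
        stale_probe_ids=stale_ids,
    )


def simulate_ground_truth(
    config: SimulationConfig,
    design: ChipDesign,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw gene expression, subgroup effects and per-sample decay scales.

    Subgroup effects are applied identically in both preservation arms, so
    frozen-arm differential expression is a valid gold standard for the
    FFPE arm.
    """
    config.validate()
    rng = rng if rng is not None else _stage_rng(config.seed, 2)
    genes = sorted(design.transcripts)
    n = config.n_samples_per_subgroup
    pairs = [f"A{i + 1:02d}" for i in range(n)] + [f"B{i + 1:02d}" for i in range(n)]
    subgroup = pd.Series(["A"] * n + ["B"] * n, index=pairs, name="subgroup")

    base = rng.normal(config.base_expression_mean, config.base_expression_sd, len(genes))
    n_de = int(round(config.frac_de_genes * len(genes)))
    de_idx = rng.choice(len(genes), size=n_de, replace=False)
    signs = rng.choice([-1, 1], size=n_de)
    de_sign = {genes[i]: int(s) for i, s in zip(de_idx, signs)}

    expr = np.tile(base[:, None], (1, len(pairs)))
    is_b = (subgroup == "B").to_numpy()
    for i, s in zip(de_idx, signs):
        expr[i, is_b] += s * config.de_effect_log2
    expr = expr + rng.normal(0.0, config.biological_sd, size=expr.shape)

    lam = rng.uniform(*config.decay_scale_range, size=len(pairs))
    return GroundTruth(
        gene_expression=pd.DataFrame(expr, index=genes, columns=pairs),
        de_gene_ids=set(de_sign),
        de_sign=de_sign,
        probe_affinity=design.probe_affinity,
        decay_scale=pd.Series(lam, index=pairs, name="decay_scale"),
        subgroup=subgroup,
    )


def _probe_distance_table(
    design: ChipDesign, hits: Sequence[ProbeHit]
) -> dict[str, list[tuple[str, int]]]:
    """probe id -> list of (gene, 3'-distance) contributions."""
    d_by_probe = {h.probe_id: h for h in hits}
    table: dict[str, list[tuple[str, int]]] = {}
    for p in design.probes:
        pid = p.probe_id
        if pid in design.background_probe_ids or pid in design.stale_probe_ids:
            continue
        if pid in design.ambiguous_sites:
            table[pid] = [
                (g, design.transcripts[g].length - (start + PROBE_LENGTH))
                for g, start in design.ambiguous_sites[pid]
            ]
        elif pid in d_by_probe:
            h = d_by_probe[pid]
            table[pid] = [(h.gene_id, h.three_prime_distance)]
        else:
            raise ConsistencyError(f"matching probe {pid!r} has no ProbeHit")
    return table


def _contribution_arrays(
    contrib: dict[str, list[tuple[str, int]]],
    signal_ids: Sequence[str],
    gene_pos: Mapping[str, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten probe->gene contributions for vectorized intensity sums."""
    rows, gidx, dist = [], [], []
    for r, pid in enumerate(signal_ids):
        for gene, d in contrib[pid]:
            rows.append(r)
            gidx.append(gene_pos[gene])
            dist.append(d)
    return np.asarray(rows), np.asarray(gidx), np.asarray(dist, dtype=float)


def simulate_matched_arrays(
    design: ChipDesign,
    hits: Sequence[ProbeHit],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Raw probe x sample intensity matrices for the two preservation arms.

    Returns ``(frozen, ffpe, annotation)``; annotation rows carry sample
    id, subgroup, preservation and matched-pair id.  Non-matching (stale
    and decoy) probes receive background-only intensities drawn log-
    normally around the 5th percentile of matching-probe intensities.
    """
    config.validate()
    rng = rng if rng is not None else _stage_rng(config.seed, 3)
    contrib = _probe_distance_table(design, hits)
    probe_order = [p.probe_id for p in design.probes]
    pairs = list(truth.gene_expression.columns)
    lam = truth.decay_scale

    signal_ids = [pid for pid in probe_order if pid in contrib]
    nonmatching = [pid for pid in probe_order if pid not in contrib]

    expr = truth.gene_expression
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    rows, gidx, dist = _contribution_arrays(contrib, signal_ids, gene_pos)
    a = design.probe_affinity[signal_ids].to_numpy()
    expr_arr = expr.to_numpy()

    pure = 2.0 ** (expr_arr[gidx, :] + a[rows][:, None])  # one row per contribution
    frozen = np.zeros((len(signal_ids), len(pairs)))
    ffpe = np.zeros_like(frozen)
    np.add.at(frozen, rows, pure)
    np.add.at(ffpe, rows, pure * np.exp(-dist[:, None] / lam.to_numpy()[None, :]))
    # measurement noise is multiplicative (log-normal) on the hybridized signal
    frozen *= 2.0 ** rng.normal(0.0, config.noise_sd_frozen, size=frozen.shape)
    ffpe *= 2.0 ** rng.normal(0.0, config.noise_sd_ffpe, size=ffpe.shape)
    if config.additive_background:
        frozen += 2.0 ** rng.normal(
            config.background_log2, config.background_sd, size=frozen.shape
        )
        ffpe += 2.0 ** rng.normal(
            config.background_log2, config.background_sd, size=ffpe.shape
        )

    def add_background_rows(mat: np.ndarray) -> np.ndarray:
        if not nonmatching:
            return mat
        p5 = np.percentile(mat, 5.0, axis=0)
        bg = 2.0 ** (
            np.log2(p5)[None, :]
            + rng.normal(0.0, config.background_sd, size=(len(nonmatching), mat.shape[1]))
        )
        return np.vstack([mat, bg])

    frozen = add_background_rows(frozen)
    ffpe = add_background_rows(ffpe)
    row_index = signal_ids + nonmatching

    frozen_cols = [f"{p}_FF" for p in pairs]
    ffpe_cols = [f"{p}_PE" for p in pairs]
    frozen_df = (
        pd.DataFrame(frozen, index=row_index, columns=frozen_cols)
        .reindex(probe_order)
    )
    ffpe_df = pd.DataFrame(ffpe, index=row_index, columns=ffpe_cols).reindex(probe_order)
    frozen_df.index.name = ffpe_df.index.name = "probe_id"

    ann = pd.DataFrame(
        {
            "sample_id": frozen_cols + ffpe_cols,
            "subgroup": list(truth.subgroup) * 2,
            "preservation": ["frozen"] * len(pairs) + ["ffpe"] * len(pairs),
            "pair_id": pairs * 2,
        }
    )
    return frozen_df, ffpe_df, ann


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: transcriptome, chip, truth, matched arrays.

    All randomness derives from ``config.seed``; the same config yields
    bit-identical outputs.
    """
    config.validate()
    transcripts = simulate_transcriptome(config)
    design = simulate_chip_design(transcripts, config)
    hits = map_probes(design.probes, design.transcripts)
    truth = simulate_ground_truth(config, design)
    frozen, ffpe, ann = simulate_matched_arrays(design, hits, truth, config)
    return SimulatedDataset(
        config=config,
        transcripts=design.transcripts,
        probes=design.probes,
        design=design,
        hits=hits,
        truth=truth,
        frozen=frozen,
        ffpe=ffpe,
        annotation=ann,
    )


def simulate_reference_batches(
    dataset: SimulatedDataset,
    n_batches: int = 20,
    batch_size: int = 5,
    batch_effect_sd: float = 0.1,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Frozen-type reference arrays for frozen-parameter estimation.

    Emulates a public-repository reference pool: fresh biological draws
    around the same gene baseline, organized in batches with a small
    per-batch per-probe shift (``batch_effect_sd``, log2) so between-batch
    variance components are estimable.  No FFPE decay.
    """
    config = dataset.config
    rng = _stage_rng(config.seed if seed is None else seed, 7)
    contrib = _probe_distance_table(dataset.design, dataset.hits)
    probe_order = [p.probe_id for p in dataset.probes]
    signal_ids = [pid for pid in probe_order if pid in contrib]
    nonmatching = [pid for pid in probe_order if pid not in contrib]
    genes = sorted(dataset.transcripts)
    base = dataset.truth.gene_expression.mean(axis=1).reindex(genes).to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows, gidx, _dist = _contribution_arrays(contrib, signal_ids, gene_pos)
    a = dataset.design.probe_affinity[signal_ids].to_numpy()

    batches = []
    for b in range(n_batches):
        batch_shift = rng.normal(0.0, batch_effect_sd, size=len(signal_ids))
        g = base[:, None] + rng.normal(0.0, config.biological_sd, size=(len(genes), batch_size))
        pure = 2.0 ** (g[gidx, :] + (a + batch_shift)[rows][:, None])
        sig = np.zeros((len(signal_ids), batch_size))
        np.add.at(sig, rows, pure)
        sig *= 2.0 ** rng.normal(0.0, config.noise_sd_frozen, size=sig.shape)
        if config.additive_background:
            sig += 2.0 ** rng.normal(
                config.background_log2, config.background_sd, size=sig.shape
            )
        mat = pd.DataFrame(
            sig,
            index=signal_ids,
            columns=[f"ref_b{b:02d}_s{s}" for s in range(batch_size)],
        )
        if nonmatching:
            p5 = np.percentile(mat.to_numpy(), 5.0, axis=0)
            bg = 2.0 ** (
                np.log2(p5)[None, :]
                + rng.normal(0.0, config.background_sd, size=(len(nonmatching), mat.shape[1]))
            )
            mat = pd.concat([mat, pd.DataFrame(bg, index=nonmatching, columns=mat.columns)])
        mat = mat.reindex(probe_order)
        mat.index.name = "probe_id"
        batches.append(mat)
    return batches
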