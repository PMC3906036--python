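"""Probe re-annotation and alternative chip-description construction.

Short oligonucleotide arrays summarize each gene from a group of 25-mer
probes (a *probeset*) defined by a chip description that reflects the
transcript annotation available when the array was designed.  As annotation
improves, many probes no longer match any current transcript, match more
than one gene, or sit far from the 3' end where degraded RNA loses signal.
This module re-annotates probes against a one-isoform-per-gene
transcriptome by exact 25-mer matching and builds two alternative chip
descriptions:

``refseq_all``
    one probeset per gene containing *all* probes that map uniquely to that
    gene's transcript (genes with fewer than ``min_probes`` such probes are
    dropped); probesets that were split across several original probesets
    are merged.

``refseq_dist``
    one probeset per gene containing only the probes closest to the 3' end
    (at most ``n_dist_probes``), all required to lie within
    ``distance_cutoff`` base pairs of the 3' terminus.  Because degraded
    RNA is sequenced/amplified from the 3' end, these probes are the most
    reliable on archival material.

Coordinates are 0-based, half-open.  The 3' distance of a probe is measured
from its 3'-most aligned base to the transcript end:
``d = length - (match_start + 25)``.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, ValidationError

PROBE_LENGTH = 25

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A single transcript sequence attributed to one gene."""

    gene_id: str
    transcript_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Probe:
    """A 25-mer array probe and the vendor probeset it belongs to."""

    probe_id: str
    probeset_id: str
    sequence: str
    x: int | None = None
    y: int | None = None

    def __post_init__(self):
        if len(self.sequence) != PROBE_LENGTH:
            raise ValidationError(
                f"probe {self.probe_id!r}: sequence length "
                f"{len(self.sequence)} != {PROBE_LENGTH}"
            )


@dataclass(frozen=True)
class ProbeHit:
    """A unique probe-to-gene match.

    ``three_prime_distance`` is the number of bases between the probe's
    3'-most aligned base and the transcript's 3' end.
    """

    probe_id: str
    gene_id: str
    match_start: int
    three_prime_distance: int


@dataclass
class ChipDescription:
    """Mapping from probesets to ordered probe lists.

    ``variant`` distinguishes the vendor grouping (``standard``) from the
    two re-annotated groupings.  ``gene_ids`` maps probeset id to gene id
    where known (always for the alternative variants).  ``distances``
    carries the 3' distance of each probe where known.
    """

    name: str
    variant: str
    probesets: dict[str, list[str]]
    gene_ids: dict[str, str] = field(default_factory=dict)
    distances: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in {"standard", "refseq_all", "refseq_dist"}:
            raise ValidationError(f"unknown chip-description variant {self.variant!r}")
        seen: dict[str, str] = {}
        for ps, members in self.probesets.items():
            if len(set(members)) != len(members):
                raise ValidationError(f"duplicate probe within probeset {ps!r}")
            for p in members:
                if p in seen:
                    raise ValidationError(
                        f"probe {p!r} appears in probesets {seen[p]!r} and {ps!r}"
                    )
                seen[p] = ps

    @property
    def n_probesets(self) -> int:
        return len(self.probesets)

    def probe_ids(self) -> list[str]:
        """All probe ids in probeset order."""
        return [p for members in self.probesets.values() for p in members]

    def genes(self) -> set[str]:
        return set(self.gene_ids.values())


def select_longest_isoform(records: Iterable[Transcript]) -> dict[str, Transcript]:
    """Collapse a multi-isoform transcript set to one transcript per gene.

    The longest isoform wins; equal-length ties are broken by the
    lexicographically smallest transcript id, for determinism.
    """
    best: dict[str, Transcript] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or rec.length > cur.length
            or (rec.length == cur.length and rec.transcript_id < cur.transcript_id)
        ):
            best[rec.gene_id] = rec
    return best


def map_probes(
    probes: Iterable[Probe],
    transcripts: Mapping[str, Transcript],
    revcomp_probes: bool = False,
) -> list[ProbeHit]:
    """Match probes exactly against transcripts; keep only unambiguous hits.

    A probe yields a hit iff its sequence (reverse-complemented first when
    ``revcomp_probes`` is set, for probe tables stored in array
    orientation) occurs with no mismatches in exactly one gene's
    transcript.  Probes matching zero genes or two or more genes are
    silently dropped — only unambiguously mapping probes are trusted.  A
    probe matching one gene at several positions keeps the most-3' match
    (minimal 3' distance).
    """
    probes = list(probes)
    for p in probes:
        if len(p.sequence) != PROBE_LENGTH:  # defensive; Probe validates too
            raise ValidationError(f"probe {p.probe_id!r} is not {PROBE_LENGTH} nt")
    # Several probes may share one sequence; index sequence -> probe ids.
    by_seq: dict[str, list[str]] = defaultdict(list)
    for p in probes:
        seq = reverse_complement(p.sequence) if revcomp_probes else p.sequence
        by_seq[seq.upper()].append(p.probe_id)

    # One linear scan over every transcript, recording occurrences of any
    # probe sequence.  dict lookup on the 25-mer window keeps this O(total
    # transcript length).
    occ: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for t in transcripts.values():
        seq = t.sequence
        for i in range(len(seq) - PROBE_LENGTH + 1):
            window = seq[i : i + PROBE_LENGTH]
            if window in by_seq:
                occ[window].append((t.gene_id, i))

    hits: list[ProbeHit] = []
    for seq, probe_ids in by_seq.items():
        matches = occ.get(seq)
        if not matches:
            continue
        genes = {g for g, _ in matches}
        if len(genes) != 1:
            continue  # ambiguous: excluded
        gene = next(iter(genes))
        start = max(i for _, i in matches)  # most-3' match
        d = transcripts[gene].length - (start + PROBE_LENGTH)
        for pid in probe_ids:
            hits.append(ProbeHit(pid, gene, start, d))
    hits.sort(key=lambda h: h.probe_id)
    return hits


def _hits_by_gene(hits: Iterable[ProbeHit]) -> dict[str, list[ProbeHit]]:
    grouped: dict[str, list[ProbeHit]] = defaultdict(list)
    for h in hits:
        grouped[h.gene_id].append(h)
    return grouped


def build_refseq_all(
    hits: Iterable[ProbeHit],
    min_probes: int = 5,
    name: str = "refseq_all",
) -> ChipDescription:
    """Merge all uniquely mapping probes of each gene into one probeset.

    Genes supported by fewer than ``min_probes`` unique probes are dropped.
    Probes are ordered by increasing 3' distance (ties by probe id).
    """
    probesets: dict[str, list[str]] = {}
    gene_ids: dict[str, str] = {}
    distances: dict[str, int] = {}
    for gene, ghits in sorted(_hits_by_gene(hits).items()):
        if len(ghits) < min_probes:
            continue
        ghits.sort(key=lambda h: (h.three_prime_distance, h.probe_id))
        probesets[gene] = [h.probe_id for h in ghits]
        gene_ids[gene] = gene
        for h in ghits:
            distances[h.probe_id] = h.three_prime_distance
    return ChipDescription(name, "refseq_all", probesets, gene_ids, distances)


def build_refseq_dist(
    hits: Iterable[ProbeHit],
    n_dist_probes: int = 5,
    distance_cutoff: int = 300,
    min_dist_probes: int = 5,
    name: str = "refseq_dist",
) -> ChipDescription:
    """Keep, per gene, the probes closest to the 3' end.

    Candidates are unique hits within ``distance_cutoff`` bp of the 3'
    terminus; the ``n_dist_probes`` with smallest distance are retained
    (distance ties broken by probe id).  Genes with fewer than
    ``min_dist_probes`` candidates are dropped.
    """
    probesets: dict[str, list[str]] = {}
    gene_ids: dict[str, str] = {}
    distances: dict[str, int] = {}
    for gene, ghits in sorted(_hits_by_gene(hits).items()):
        cand = [h for h in ghits if h.three_prime_distance <= distance_cutoff]
        if len(cand) < min_dist_probes:
            continue
        cand.sort(key=lambda h: (h.three_prime_distance, h.probe_id))
        chosen = cand[:n_dist_probes]
        probesets[gene] = [h.probe_id for h in chosen]
        gene_ids[gene] = gene
        for h in chosen:
            distances[h.probe_id] = h.three_prime_distance
    return ChipDescription(name, "refseq_dist", probesets, gene_ids, distances)


def build_standard_description(
    probes: Iterable[Probe],
    name: str = "standard",
) -> ChipDescription:
    """Group probes by their vendor probeset id, preserving probe order."""
    probesets: dict[str, list[str]] = {}
    for p in probes:
        probesets.setdefault(p.probeset_id, []).append(p.probe_id)
    return ChipDescription(name, "standard", probesets)


def restrict_to_common_genes(
    standard_cd: ChipDescription,
    alt_cd: ChipDescription,
    annotation: Mapping[str, str],
    name: str | None = None,
) -> ChipDescription:
    """Filter a standard description to probesets targeting genes covered
    by an alternative description (for like-for-like benchmarking).

    ``annotation`` maps standard probeset ids to gene ids; unannotated
    probesets are dropped with a warning.
    """
    alt_genes = alt_cd.genes()
    probesets: dict[str, list[str]] = {}
    gene_ids: dict[str, str] = {}
    distances: dict[str, int] = {}
    for ps, members in standard_cd.probesets.items():
        gene = annotation.get(ps, standard_cd.gene_ids.get(ps))
        if gene is None:
            warnings.warn(f"standard probeset {ps!r} has no gene annotation; dropped")
            continue
        if gene in alt_genes:
            probesets[ps] = list(members)
            gene_ids[ps] = gene
            for p in members:
                if p in standard_cd.distances:
                    distances[p] = standard_cd.distances[p]
    return ChipDescription(
        name or f"{standard_cd.name}_common_{alt_cd.name}",
        "standard",
        probesets,
        gene_ids,
        distances,
    )


def select_max_iqr_probesets(
    standard_cd: ChipDescription,
    annotation: Mapping[str, str],
    expression,
    name: str = "standard_max_iqr",
) -> ChipDescription:
    """Keep one probeset per gene: the one with the largest expression IQR.

    A deliberately simple stand-in for published per-gene probeset
    selection methods, useful for benchmark arms that require a single
    probeset per gene.  ``expression`` is a probeset x sample matrix used
    only to rank probesets; IQR ties break toward the smaller probeset id.
    Unannotated probesets are dropped with a warning.
    """
    iqr = expression.quantile(0.75, axis=1) - expression.quantile(0.25, axis=1)
    best: dict[str, tuple[float, str]] = {}
    for ps in standard_cd.probesets:
        gene = annotation.get(ps, standard_cd.gene_ids.get(ps))
        if gene is None:
            warnings.warn(f"standard probeset {ps!r} has no gene annotation; dropped")
            continue
        if ps not in iqr.index:
            warnings.warn(f"probeset {ps!r} absent from expression matrix; dropped")
            continue
        key = (-float(iqr[ps]), ps)
        if gene not in best or key < best[gene]:
            best[gene] = key
    keep = {ps for _, ps in best.values()}
    probesets = {
        ps: list(members)
        for ps, members in standard_cd.probesets.items()
        if ps in keep
    }
    kept_probes = {p for members in probesets.values() for p in members}
    return ChipDescription(
        name,
        "standard",
        probesets,
        {ps: annotation.get(ps, standard_cd.gene_ids.get(ps)) for ps in keep},
        {p: d for p, d in standard_cd.distances.items() if p in kept_probes},
    )


_CDF_HEADER = ["probeset_id", "gene_id", "probe_id", "rank", "three_prime_distance"]


def write_cdf(cd: ChipDescription, path) -> None:
    """Serialize a chip description as TSV (one probe per line)."""
    with open(path, "w") as fh:
        fh.write(f"# chip_description\tname={cd.name}\tvariant={cd.variant}\n")
        fh.write("\t".join(_CDF_HEADER) + "\n")
        for ps, members in cd.probesets.items():
            gene = cd.gene_ids.get(ps, "NA")
            for rank, probe in enumerate(members, start=1):
                d = cd.distances.get(probe)
                fh.write(
                    f"{ps}\t{gene}\t{probe}\t{rank}\t{'NA' if d is None else d}\n"
                )


def read_cdf(path) -> ChipDescription:
    """Parse a chip description written by :func:`write_cdf`.

    Malformed lines raise :class:`ParseError` with the line number; a
    duplicate probe within a probeset is rejected.
    """
    probesets: dict[str, list[str]] = {}
    gene_ids: dict[str, str] = {}
    distances: dict[str, int] = {}
    name, variant = "unnamed", "standard"
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    if lines and lines[0].startswith("# chip_description"):
        for token in lines[0].split("\t")[1:]:
            key, _, val = token.partition("=")
            if key == "name":
                name = val
            elif key == "variant":
                variant = val
        body_start = 1
    if body_start < len(lines) and lines[body_start].startswith("probeset_id"):
        body_start += 1
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(
                f"expected 5 tab-separated fields, found {len(fields)}",
                path=path,
                line=lineno,
            )
        ps, gene, probe, rank_s, d_s = fields
        try:
            int(rank_s)
        except ValueError:
            raise ParseError(f"invalid rank {rank_s!r}", path=path, line=lineno)
        members = probesets.setdefault(ps, [])
        if probe in members:
            raise ParseError(
                f"duplicate probe {probe!r} in probeset {ps!r}", path=path, line=lineno
            )
        members.append(probe)
        if gene != "NA":
            gene_ids[ps] = gene
        if d_s != "NA":
            try:
                distances[probe] = int(d_s)
            except ValueError:
                raise ParseError(
                    f"invalid three_prime_distance {d_s!r}", path=path, line=lineno
                )
    try:
        return ChipDescription(name, variant, probesets, gene_ids, distances)
    except ValidationError as exc:
        raise ParseError(str(exc), path=path) from exc


def write_probe_hits(hits: Sequence[ProbeHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_id\tmatch_start\tthree_prime_distance\n")
        for h in hits:
            fh.write(
                f"{h.probe_id}\t{h.gene_id}\t{h.match_start}\t{h.three_prime_distance}\n"
            )


def read_probe_hits(path) -> list[ProbeHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("probe_id"):
            raise ParseError("missing probe-hit header", path=path, line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ParseError("expected 4 fields", path=path, line=lineno)
            try:
                hits.append(
                    ProbeHit(fields[0], fields[1], int(fields[2]), int(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno)
    return hits
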