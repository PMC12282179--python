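"""Synthetic strain panels with planted ground truth.

This module fabricates everything the pipeline consumes — multi-contig
bacterial assemblies carrying type I-E and II-C CRISPR arrays (canonical
and orphan placements), Cas-operon and decoy gene annotations, prophage
regions that donate protospacers, shared spacers between strains, and
paired reads from a mixed community including a host decoy genome — and
records the exact coordinates and provenance of every planted feature in
a truth table, so each downstream stage can be scored against known
answers.

Layout rules
------------
Features are placed sequentially on each contig with inter-feature gaps
of at least 600 bp, which keeps the canonical/orphan 500-bp proximity
rule unambiguous: a canonical array sits 50-300 bp downstream of its own
Cas operon, and everything else is farther than 500 bp from any Cas
gene.  Planted arrays are also *boundary-disambiguated*: the genome
columns immediately flanking each repeat copy are guaranteed not to
reach the detector's 75% column-agreement level, so the planted
repeat/spacer boundaries are the unique boundaries a structure-based
detector can report.

One integer seed drives a single ``numpy`` generator; draws happen in
plan order (strain by strain, arrays, prophages, genes, then contig
backbones), so equal plans plus an equal seed give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .array_detection import BOUNDARY_AGREEMENT
from .repeat_typing import (
    DEFAULT_IIC_REPEAT,
    RepeatCatalog,
    build_ie_repeat,
    fold_hairpin,
)
from .seqs import DNA_ALPHABET, canonical, mutate, random_dna, revcomp

#: tetraloop assigned by default to canonical / orphan I-E arrays
DEFAULT_LOOPS = {"canonical": "GTTC", "orphan": "TTCG"}

_IE_OPERON = ["cas3", "cse1", "cse2", "cas7", "cas5", "cas6e", "cas1", "cas2"]
_IIC_OPERON = ["cas9", "cas1", "cas2"]


@dataclasses.dataclass
class ArrayPlan:
    """One planted CRISPR array."""

    system_type: str  # {"I-E", "II-C"}
    context: str  # {"canonical", "orphan"}
    n_spacers: int
    repeat_seq: str | None = None
    tetraloop: str | None = None  # I-E only
    spacer_len: int = 32
    spacer_sources: list[str] | None = None  # per spacer: random | prophage:<id> | shared:<strain>:<array>:<index>
    mutation_rate: float = 0.0  # substitutions applied to sourced spacer copies

    def __post_init__(self) -> None:
        if self.system_type not in ("I-E", "II-C"):
            raise ValueError(f"unknown system type {self.system_type!r}")
        if self.context not in ("canonical", "orphan"):
            raise ValueError(f"unknown context {self.context!r}")
        if self.n_spacers < 1:
            raise ValueError("an array needs at least one spacer")
        if self.spacer_sources is not None and len(self.spacer_sources) != self.n_spacers:
            raise ValueError("spacer_sources must have one entry per spacer")

    def resolve_repeat(self) -> str:
        if self.repeat_seq is not None:
            rep = self.repeat_seq
        elif self.system_type == "I-E":
            loop = self.tetraloop or DEFAULT_LOOPS[self.context]
            rep = build_ie_repeat(loop)
        else:
            rep = DEFAULT_IIC_REPEAT
        if not 23 <= len(rep) <= 40:
            raise ValueError(f"repeat length {len(rep)} outside [23, 40]")
        if self.system_type == "I-E":
            hp = fold_hairpin(rep)
            want = self.tetraloop or DEFAULT_LOOPS[self.context]
            if self.repeat_seq is None and (hp is None or hp.loop_seq != want):
                raise ValueError("planted I-E repeat does not fold to its tetraloop")
        return rep


@dataclasses.dataclass
class ProphagePlan:
    prophage_id: str
    length: int
    completeness: str  # {intact, questionable, incomplete}

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("prophage regions must be at least 1 kb")
        if self.completeness not in ("intact", "questionable", "incomplete"):
            raise ValueError(f"unknown completeness {self.completeness!r}")


@dataclasses.dataclass
class StrainPlan:
    strain_id: str
    n_contigs: int
    contig_lengths: list[int]
    arrays: list[ArrayPlan] = dataclasses.field(default_factory=list)
    prophages: list[ProphagePlan] = dataclasses.field(default_factory=list)
    genes: int = 4  # decoy (non-Cas) gene annotations

    def __post_init__(self) -> None:
        if len(self.contig_lengths) != self.n_contigs:
            raise ValueError("contig_lengths must match n_contigs")


@dataclasses.dataclass
class TruthTable:
    """Planted coordinates and provenance; all coordinates 0-based half-open."""

    arrays: pd.DataFrame
    spacers: pd.DataFrame
    prophages: pd.DataFrame
    genes: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("arrays", "spacers", "prophages", "genes"):
            cio.write_tsv(getattr(self, name), outdir / f"truth.{name}.tsv")


@dataclasses.dataclass
class StrainPanel:
    """In-memory panel: assemblies, annotations, prophage calls and truth."""

    assemblies: dict[str, dict[str, str]]  # strain -> contig -> seq
    gff: dict[str, list[cio.GffFeature]]
    prophage_bed: pd.DataFrame
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for strain, contigs in self.assemblies.items():
            cio.write_fasta(contigs, outdir / f"{strain}.fasta")
            cio.write_gff(self.gff[strain], outdir / f"{strain}.gff3")
        cio.write_prophage_bed(self.prophage_bed, outdir / "prophages.bed")
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# feature construction


class _Feature:
    """A placed block of sequence plus its annotation callbacks."""

    def __init__(self, kind: str, seq: str, payload: dict):
        self.kind = kind
        self.seq = seq
        self.payload = payload
        self.start = -1  # assigned at layout time

    def __len__(self) -> int:
        return len(self.seq)


def _draw_gene_lengths(rng: np.random.Generator, n: int) -> list[int]:
    return [int(rng.integers(300, 900)) for _ in range(n)]


def _make_operon(
    rng: np.random.Generator, names: list[str]
) -> tuple[str, list[tuple[str, int, int]]]:
    """Random gene run with 20-60 bp intergenic gaps; returns seq + offsets."""
    seq_parts: list[str] = []
    offsets = []
    cursor = 0
    for i, name in enumerate(names):
        if i > 0:
            gap = int(rng.integers(20, 60))
            seq_parts.append(random_dna(rng, gap))
            cursor += gap
        length = int(rng.integers(400, 1000))
        seq_parts.append(random_dna(rng, length))
        offsets.append((name, cursor, cursor + length))
        cursor += length
    return "".join(seq_parts), offsets


def _disambiguate_boundary(
    bases: list[str],
    free: list[int],
    rng: np.random.Generator,
) -> list[str]:
    """Redraw free entries until no base reaches the column-agreement level.

    ``bases`` holds the genome column flanking each repeat copy of one
    array (one entry per copy).  Entries listed in ``free`` may be
    redrawn (random spacers and backbone flanks); fixed entries belong
    to prophage-sourced or shared spacers.
    """
    n = len(bases)
    threshold = math.ceil(BOUNDARY_AGREEMENT * n)

    def ok(b: list[str]) -> bool:
        return max(b.count(x) for x in set(b)) < threshold

    if ok(bases):
        return bases
    for _ in range(200):
        out = list(bases)
        for i in free:
            out[i] = DNA_ALPHABET[rng.integers(4)]
        if ok(out):
            return out
    raise ValueError(
        "cannot disambiguate array boundary: too many fixed-source spacers share a flanking base"
    )


def _build_array_feature(
    rng: np.random.Generator,
    strain_id: str,
    array_index: int,
    plan: ArrayPlan,
    spacer_seqs: list[str],
    spacer_meta: list[dict],
    free_spacers: list[int],
) -> _Feature:
    repeat = plan.resolve_repeat()
    n = plan.n_spacers + 1  # repeat copies

    # boundary disambiguation (see module docstring)
    left = [s[-1] for s in spacer_seqs] + [DNA_ALPHABET[rng.integers(4)]]
    left = _disambiguate_boundary(left, free_spacers + [len(left) - 1], rng)
    right = [s[0] for s in spacer_seqs] + [DNA_ALPHABET[rng.integers(4)]]
    right = _disambiguate_boundary(right, free_spacers + [len(right) - 1], rng)
    spacer_seqs = [s[:-1] + left[i] for i, s in enumerate(spacer_seqs)]
    spacer_seqs = [right[i] + s[1:] for i, s in enumerate(spacer_seqs)]
    flank_left, flank_right = left[-1], right[-1]

    parts = [flank_left]
    spacer_offsets = []
    cursor = 1
    for i in range(n):
        parts.append(repeat)
        cursor += len(repeat)
        if i < plan.n_spacers:
            parts.append(spacer_seqs[i])
            spacer_offsets.append((cursor, cursor + len(spacer_seqs[i])))
            cursor += len(spacer_seqs[i])
    parts.append(flank_right)
    seq = "".join(parts)
    return _Feature(
        "array",
        seq,
        {
            "strain_id": strain_id,
            "array_index": array_index,
            "plan": plan,
            "repeat": repeat,
            "array_off": (1, cursor),  # array proper, inside the flanked block
            "spacer_offsets": spacer_offsets,
            "spacer_seqs": spacer_seqs,
            "spacer_meta": spacer_meta,
        },
    )


# ---------------------------------------------------------------------------
# panel assembly


def build_strain_panel(
    plans: list[StrainPlan],
    repeat_catalog: RepeatCatalog | None = None,
    seed: int = 0,
) -> StrainPanel:
    """Materialise a panel of strains from plans, with full planted truth.

    The repeat catalog is only consulted for defaults; explicit
    ``repeat_seq`` entries in plans win.  Raises ``ValueError`` when a
    plan cannot be honoured (features exceeding contig length,
    unresolvable shared-spacer references, overlapping placements).
    """
    del repeat_catalog  # defaults come from repeat_typing's constants
    rng = np.random.default_rng(seed)
    ids = [p.strain_id for p in plans]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in plans")

    # pass 1: prophage sequences (spacer donors)
    prophage_seqs: dict[str, str] = {}
    prophage_owner: dict[str, tuple[str, ProphagePlan]] = {}
    for plan in plans:
        for pp in plan.prophages:
            if pp.prophage_id in prophage_seqs:
                raise ValueError(f"duplicate prophage id {pp.prophage_id!r}")
            prophage_seqs[pp.prophage_id] = random_dna(rng, pp.length)
            prophage_owner[pp.prophage_id] = (plan.strain_id, pp)

    # spacers referenced by shared: sources must stay byte-identical in the
    # donor genome, so they are pinned against boundary redraws
    donors: set[tuple[str, int, int]] = set()
    for plan in plans:
        for ap in plan.arrays:
            for src in ap.spacer_sources or []:
                if src.startswith("shared:"):
                    ref = src.split(":", 1)[1].replace(",", ":").split(":")
                    if len(ref) != 3:
                        raise ValueError(f"malformed shared spacer source {src!r}")
                    donors.add((ref[0], int(ref[1]), int(ref[2])))

    # pass 2: resolve spacer sequences in plan order
    resolved: dict[tuple[str, int, int], str] = {}  # (strain, array, index) -> seq
    spacer_meta_all: dict[tuple[str, int], list[dict]] = {}
    spacer_seqs_all: dict[tuple[str, int], list[str]] = {}
    free_all: dict[tuple[str, int], list[int]] = {}
    for plan in plans:
        for ai, ap in enumerate(plan.arrays):
            sources = ap.spacer_sources or ["random"] * ap.n_spacers
            seqs: list[str] = []
            metas: list[dict] = []
            free: list[int] = []
            for si, src in enumerate(sources):
                meta = {"source": src, "prophage_id": "", "proto_start": -1,
                        "proto_end": -1, "proto_strand": "."}
                if src == "random":
                    while True:
                        s = random_dna(rng, ap.spacer_len)
                        if canonical(s) not in {canonical(x) for x in seqs}:
                            break
                    if (plan.strain_id, ai, si) not in donors:
                        free.append(si)
                elif src.startswith("prophage:"):
                    pid = src.split(":", 1)[1]
                    if pid not in prophage_seqs:
                        raise ValueError(f"unknown prophage id {pid!r} in spacer source")
                    donor = prophage_seqs[pid]
                    if ap.spacer_len > len(donor):
                        raise ValueError("spacer longer than donor prophage")
                    pstart = int(rng.integers(0, len(donor) - ap.spacer_len + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    s = donor[pstart : pstart + ap.spacer_len]
                    if strand == "-":
                        s = revcomp(s)
                    s = mutate(s, ap.mutation_rate, rng)
                    meta.update(
                        prophage_id=pid,
                        proto_start=pstart,
                        proto_end=pstart + ap.spacer_len,
                        proto_strand=strand,
                    )
                elif src.startswith("shared:"):
                    ref = src.split(":", 1)[1].replace(",", ":").split(":")
                    if len(ref) != 3:
                        raise ValueError(f"malformed shared spacer source {src!r}")
                    key = (ref[0], int(ref[1]), int(ref[2]))
                    if key not in resolved:
                        raise ValueError(
                            f"shared spacer source {src!r} refers to a spacer not yet planted; "
                            "order plans so donors precede recipients"
                        )
                    s = resolved[key]
                else:
                    raise ValueError(f"unknown spacer source {src!r}")
                seqs.append(s)
                metas.append(meta)
                resolved[(plan.strain_id, ai, si)] = s
            spacer_seqs_all[(plan.strain_id, ai)] = seqs
            spacer_meta_all[(plan.strain_id, ai)] = metas
            free_all[(plan.strain_id, ai)] = free

    # pass 3: build features and lay out contigs
    assemblies: dict[str, dict[str, str]] = {}
    gff: dict[str, list[cio.GffFeature]] = {}
    bed_rows = []
    truth_arrays = []
    truth_spacers = []
    truth_prophages = []
    truth_genes = []

    for plan in plans:
        features_per_contig: list[list[_Feature]] = [[] for _ in range(plan.n_contigs)]
        orphan_contig = 1 % plan.n_contigs  # keep contig 0 for Cas-bearing features
        rr = {"prophage": 0, "gene": 0, "orphan": orphan_contig}

        for ai, ap in enumerate(plan.arrays):
            arr_feat = _build_array_feature(
                rng,
                plan.strain_id,
                ai,
                ap,
                spacer_seqs_all[(plan.strain_id, ai)],
                spacer_meta_all[(plan.strain_id, ai)],
                free_all[(plan.strain_id, ai)],
            )
            # keep resolved truth in sync with boundary-disambiguated bases
            for si, s in enumerate(arr_feat.payload["spacer_seqs"]):
                resolved[(plan.strain_id, ai, si)] = s
            if ap.context == "canonical":
                names = _IE_OPERON if ap.system_type == "I-E" else _IIC_OPERON
                op_seq, op_genes = _make_operon(rng, names)
                tracr = ""
                tracr_len = 0
                if ap.system_type == "II-C":
                    rep = arr_feat.payload["repeat"]
                    tracr = revcomp(rep[: max(24, len(rep) - 5)]) + random_dna(rng, 30)
                    tracr_len = len(tracr)
                lead = int(rng.integers(50, 301))
                seq = tracr + op_seq + random_dna(rng, lead) + arr_feat.seq
                feat = _Feature(
                    "canonical_block",
                    seq,
                    {
                        "operon_genes": [
                            (nm, s0 + tracr_len, e0 + tracr_len) for nm, s0, e0 in op_genes
                        ],
                        "tracr_len": tracr_len,
                        "array_feat": arr_feat,
                        "array_shift": tracr_len + len(op_seq) + lead,
                    },
                )
                features_per_contig[0].append(feat)
            else:
                c = rr["orphan"]
                features_per_contig[c].append(arr_feat)
                rr["orphan"] = (c + 1) % plan.n_contigs or orphan_contig

        for pp in plan.prophages:
            c = rr["prophage"] % plan.n_contigs
            rr["prophage"] += 1
            features_per_contig[c].append(
                _Feature("prophage", prophage_seqs[pp.prophage_id], {"plan": pp})
            )
        for gi, glen in enumerate(_draw_gene_lengths(rng, plan.genes)):
            c = rr["gene"] % plan.n_contigs
            rr["gene"] += 1
            features_per_contig[c].append(
                _Feature("gene", random_dna(rng, glen), {"name": f"hyp{gi + 1:04d}"})
            )

        contigs: dict[str, str] = {}
        feats: list[cio.GffFeature] = []
        for ci in range(plan.n_contigs):
            contig_id = f"{plan.strain_id}_c{ci + 1}"
            length = plan.contig_lengths[ci]
            cursor = int(rng.integers(200, 400))
            parts = [random_dna(rng, cursor)]
            for feat in features_per_contig[ci]:
                feat.start = cursor
                parts.append(feat.seq)
                cursor += len(feat.seq)
                gap = int(rng.integers(600, 1200))
                parts.append(random_dna(rng, gap))
                cursor += gap
            if cursor > length:
                raise ValueError(
                    f"planted features exceed contig length for {contig_id} "
                    f"({cursor} > {length}); enlarge contig_lengths"
                )
            parts.append(random_dna(rng, length - cursor))
            contigs[contig_id] = "".join(parts)
            assert len(contigs[contig_id]) == length

            # annotations + truth rows
            placed: list[tuple[int, int]] = []
            for feat in features_per_contig[ci]:
                placed.append((feat.start, feat.start + len(feat.seq)))
                _emit_feature(
                    feat,
                    plan.strain_id,
                    contig_id,
                    feats,
                    bed_rows,
                    truth_arrays,
                    truth_spacers,
                    truth_prophages,
                    truth_genes,
                )
            placed.sort()
            for (s0, e0), (s1, _) in zip(placed, placed[1:]):
                if s1 < e0:
                    raise ValueError(f"planted features overlap on {contig_id}")
        assemblies[plan.strain_id] = contigs
        gff[plan.strain_id] = feats

    truth = TruthTable(
        arrays=pd.DataFrame(
            truth_arrays,
            columns=[
                "strain_id", "contig_id", "array_index", "start", "end",
                "system_type", "context", "tetraloop", "repeat", "n_spacers",
            ],
        ),
        spacers=pd.DataFrame(
            truth_spacers,
            columns=[
                "strain_id", "contig_id", "array_index", "spacer_index", "seq",
                "start", "end", "source", "prophage_id", "proto_start",
                "proto_end", "proto_strand",
            ],
        ),
        prophages=pd.DataFrame(
            truth_prophages,
            columns=["strain_id", "contig_id", "prophage_id", "start", "end", "completeness"],
        ),
        genes=pd.DataFrame(
            truth_genes,
            columns=["strain_id", "contig_id", "gene_id", "name", "start", "end", "is_cas"],
        ),
    )
    bed = pd.DataFrame(
        bed_rows,
        columns=["contig_id", "start", "end", "region_id", "score", "strand", "completeness"],
    )
    return StrainPanel(assemblies=assemblies, gff=gff, prophage_bed=bed, truth=truth)


def _emit_feature(
    feat: _Feature,
    strain_id: str,
    contig_id: str,
    feats: list,
    bed_rows: list,
    truth_arrays: list,
    truth_spacers: list,
    truth_prophages: list,
    truth_genes: list,
) -> None:
    if feat.kind == "canonical_block":
        base = feat.start
        for name, s0, e0 in feat.payload["operon_genes"]:
            gid = f"{strain_id}_{contig_id}_{name}_{base + s0}"
            feats.append(
                cio.GffFeature(contig_id, "crisprcomp_sim", "gene", base + s0, base + e0,
                               "+", {"ID": gid, "Name": name})
            )
            truth_genes.append((strain_id, contig_id, gid, name, base + s0, base + e0, True))
        if feat.payload["tracr_len"]:
            feats.append(
                cio.GffFeature(contig_id, "crisprcomp_sim", "ncRNA", base,
                               base + feat.payload["tracr_len"], "-",
                               {"ID": f"{strain_id}_{contig_id}_tracr", "Name": "tracrRNA"})
            )
        arr = feat.payload["array_feat"]
        arr.start = base + feat.payload["array_shift"]
        _emit_array(arr, strain_id, contig_id, truth_arrays, truth_spacers)
    elif feat.kind == "array":
        _emit_array(feat, strain_id, contig_id, truth_arrays, truth_spacers)
    elif feat.kind == "prophage":
        pp: ProphagePlan = feat.payload["plan"]
        bed_rows.append(
            (contig_id, feat.start, feat.start + len(feat.seq), pp.prophage_id, 0, ".",
             pp.completeness)
        )
        truth_prophages.append(
            (strain_id, contig_id, pp.prophage_id, feat.start, feat.start + len(feat.seq),
             pp.completeness)
        )
    elif feat.kind == "gene":
        name = feat.payload["name"]
        gid = f"{strain_id}_{contig_id}_{name}"
        feats.append(
            cio.GffFeature(contig_id, "crisprcomp_sim", "gene", feat.start,
                           feat.start + len(feat.seq), "+", {"ID": gid, "Name": name})
        )
        truth_genes.append(
            (strain_id, contig_id, gid, name, feat.start, feat.start + len(feat.seq), False)
        )


def _emit_array(
    feat: _Feature, strain_id: str, contig_id: str, truth_arrays: list, truth_spacers: list
) -> None:
    plan: ArrayPlan = feat.payload["plan"]
    off0, off1 = feat.payload["array_off"]
    start = feat.start + off0
    end = feat.start + off1
    loop = ""
    if plan.system_type == "I-E":
        hp = fold_hairpin(feat.payload["repeat"])
        loop = hp.loop_seq if hp else "NA"
    truth_arrays.append(
        (strain_id, contig_id, feat.payload["array_index"], start, end,
         plan.system_type, plan.context, loop, feat.payload["repeat"], plan.n_spacers)
    )
    for si, ((s0, s1), seq, meta) in enumerate(
        zip(feat.payload["spacer_offsets"], feat.payload["spacer_seqs"],
            feat.payload["spacer_meta"])
    ):
        truth_spacers.append(
            (strain_id, contig_id, feat.payload["array_index"], si, seq,
             feat.start + s0, feat.start + s1, meta["source"], meta["prophage_id"],
             meta["proto_start"], meta["proto_end"], meta["proto_strand"])
        )


# ---------------------------------------------------------------------------
# read simulation


def make_host_genome(
    length: int,
    community: list[dict[str, str]],
    seed: int | np.random.Generator = 0,
    k: int = 31,
) -> str:
    """A decoy host genome guaranteed non-homologous to the community.

    Random sequence, with any window sharing a ``k``-mer (either
    strand) with a community genome redrawn.  31-mer exclusion matches
    the host filter's mapping surrogate, so no community read can be
    mistaken for host.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kmers = set()
    for assembly in community:
        for seq in assembly.values():
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                kmers.add(km)
                kmers.add(revcomp(km))
    host = list(random_dna(rng, length))
    for _ in range(20):
        dirty = False
        for i in range(length - k + 1):
            if "".join(host[i : i + k]) in kmers:
                host[i + k // 2] = DNA_ALPHABET[rng.integers(4)]
                dirty = True
        if not dirty:
            return "".join(host)
    raise RuntimeError("could not build a collision-free host genome")


def simulate_reads(
    community: list[tuple[str, dict[str, str], float]],
    host_genome: str,
    host_fraction: float,
    read_len: int = 150,
    n_pairs: int = 1000,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Paired-end reads from a mixed community plus host contamination.

    ``community`` entries are ``(name, {contig: seq}, relative
    abundance)``; abundances are normalised.  Each pair comes from one
    source genome: a fragment of 2x-3x the read length is drawn
    uniformly (position and strand), read 1 is its 5' end and read 2 the
    reverse complement of its 3' end, with i.i.d. substitution errors.
    Returns ``(reads, truth)`` where reads are ``(pair_id, r1, r2)`` and
    the truth table labels each pair's source (``host`` pairs included).
    """
    if read_len < 50:
        raise ValueError("read_len must be at least 50")
    if not 0 <= host_fraction <= 1:
        raise ValueError("host_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    weights = np.array([abun for _, _, abun in community], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("community abundances must sum to a positive value")
    weights = weights / weights.sum()

    sources: list[tuple[str, list[tuple[str, str]]]] = []
    for name, assembly, _ in community:
        sources.append((name, list(assembly.items())))
    shortest = min(
        min(len(s) for _, s in contigs) for _, contigs in sources
    )
    shortest = min(shortest, len(host_genome))
    if read_len > shortest:
        raise ValueError("read_len exceeds the shortest contig")

    reads = []
    truth_rows = []
    for pi in range(n_pairs):
        is_host = rng.random() < host_fraction
        if is_host:
            name, contigs = "host", [("host", host_genome)]
        else:
            name, contigs = sources[rng.choice(len(sources), p=weights)]
        lens = np.array([len(s) for _, s in contigs], dtype=float)
        cidx = int(rng.choice(len(contigs), p=lens / lens.sum()))
        contig_id, seq = contigs[cidx]
        frag_hi = min(3 * read_len, len(seq))
        frag_lo = min(2 * read_len, frag_hi)
        frag_len = int(rng.integers(frag_lo, frag_hi + 1))
        pos = int(rng.integers(0, len(seq) - frag_len + 1))
        frag = seq[pos : pos + frag_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        r1 = mutate(frag[:read_len], error_rate, rng)
        r2 = mutate(revcomp(frag[-read_len:]), error_rate, rng)
        pid = f"pair{pi + 1:06d}"
        reads.append((pid, r1, r2))
        truth_rows.append((pid, name, contig_id, pos, pos + frag_len, strand, is_host))
    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "source", "contig_id", "frag_start", "frag_end", "strand",
                 "is_host"],
    )
    return reads, truth


def write_paired_fastq(
    reads: list[tuple[str, str, str]], prefix: str | Path
) -> tuple[Path, Path]:
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    cio.write_fastq([(f"{pid}/1", r1) for pid, r1, _ in reads], p1)
    cio.write_fastq([(f"{pid}/2", r2) for pid, _, r2 in reads], p2)
    return p1, p2


# ---------------------------------------------------------------------------
# a ready-made study-like panel


def demo_panel_plans(n_strains: int = 20, seed: int = 7) -> list[StrainPlan]:
    """Plans mirroring the modelled study system, sized for desk runs.

    Each strain carries 1-3 arrays: most get a canonical I-E array
    (8-25 spacers), many an orphan I-E array on a second contig with a
    different tetraloop and a larger repertoire (15-40 spacers), and
    some a small canonical II-C array (3-12 spacers).  About half the
    strains carry one prophage (mixed completeness) donating a few
    protospacers, and consecutive strains share two spacers, mirroring
    related isolates with common mobile-element history.
    """
    rng = np.random.default_rng(seed)
    completeness_cycle = ["intact", "incomplete", "questionable"]
    plans: list[StrainPlan] = []
    for i in range(n_strains):
        sid = f"S{i + 1:02d}"
        arrays: list[ArrayPlan] = []
        prophages: list[ProphagePlan] = []

        has_prophage = i % 2 == 0
        if has_prophage:
            prophages.append(
                ProphagePlan(
                    prophage_id=f"{sid}_P1",
                    length=int(rng.integers(4000, 8001)),
                    completeness=completeness_cycle[(i // 2) % 3],
                )
            )

        n_canon = int(rng.integers(8, 26))
        canon_sources = ["random"] * n_canon
        if has_prophage:
            for j in range(2):
                canon_sources[j] = f"prophage:{sid}_P1"
        if i > 0 and i % 3 == 0:
            # share two spacers with the previous strain's canonical array
            # (donor arrays always have >= 8 spacers, so indices 4-5 exist
            # and are random-sourced there)
            canon_sources[-1] = f"shared:S{i:02d}:0:4"
            canon_sources[-2] = f"shared:S{i:02d}:0:5"
        arrays.append(
            ArrayPlan("I-E", "canonical", n_canon, spacer_sources=canon_sources)
        )
        if i % 4 != 3:
            arrays.append(ArrayPlan("I-E", "orphan", int(rng.integers(15, 41))))
        if i % 3 != 2:
            arrays.append(ArrayPlan("II-C", "canonical", int(rng.integers(3, 13))))
        arrays = arrays[: 1 + i % 3] if len(arrays) > 1 + i % 3 else arrays

        plans.append(
            StrainPlan(
                strain_id=sid,
                n_contigs=2,
                contig_lengths=[42000, 22000],
                arrays=arrays,
                prophages=prophages,
                genes=4,
            )
        )
    return plans
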