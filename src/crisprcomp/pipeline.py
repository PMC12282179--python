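"""End-to-end orchestration from a flat config file.

Config format: one ``key = value`` per line, ``#`` comments.  Keys:

========================  =====================================================
``outdir``                output directory (required)
``seed``                  master seed (default 0)
``simulate``              ``true`` to generate a synthetic panel first
``n_strains``             panel size when simulating (default 6)
``assemblies``            comma-separated FASTA paths (when not simulating)
``gffs``                  comma-separated GFF3 paths, aligned with assemblies
``prophage_bed``          prophage region BED; stage skipped when absent
``reads_r1`` ``reads_r2`` paired FASTQ; read stage skipped when absent
``host_fasta``            host genome for pair decontamination
``catalog``               repeat catalog TSV (default: built-in)
``min_identity``          spacer matching threshold (default 0.80)
``pad``                   prophage padding (default 32)
``power``                 semicolon-separated power specs (printed-call form)
========================  =====================================================

Each stage writes its artifacts under ``outdir/<stage>/``; a manifest
TSV records parameters and emitted files.  A missing optional input
skips the dependent stage with a logged notice; any stage error aborts
with the stage name, keeping partial outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as cio
from .array_context import classify_contexts, read_cas_genes
from .array_detection import (
    DetectionParams,
    arrays_to_table,
    spacer_fasta_records,
    strain_scan,
)
from .prophage_overlap import (
    attribute_matches,
    edge_table,
    export_edges,
    genic_summary,
    regions_from_bed,
)
from .read_spacers import (
    ReadMinerParams,
    extract_read_spacers,
    host_filter,
    merge_groups,
    rescue_known_repeats,
)
from .repeat_typing import RepeatCatalog, assign_types, tetraloop_census
from .spacer_matching import (
    match_spacers_to_reference,
    matches_to_table,
    sharing_matrix,
    spacers_from_arrays,
)
from .stats import DistributionSpec, PowerSpec, array_size_summary, wmw_power
from .synthetic_data import (
    build_strain_panel,
    demo_panel_plans,
    make_host_genome,
    simulate_reads,
    write_paired_fastq,
)

log = logging.getLogger("crisprcomp")


def read_config(path: str | Path) -> dict[str, str]:
    cfg: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        k, v = line.split("=", 1)
        cfg[k.strip()] = v.strip()
    return cfg


def run_all(config_path: str | Path) -> Path:
    cfg = read_config(config_path)
    if "outdir" not in cfg:
        raise ValueError("config must set outdir")
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", "0"))
    manifest: list[dict] = []

    def record(stage: str, artifact: Path) -> None:
        manifest.append({"stage": stage, "artifact": str(artifact), "seed": seed,
                         "version": __version__})

    stage = "simulate"
    try:
        assemblies, gffs, prophage_bed, reads_r1, reads_r2, host_fasta = _stage_simulate(
            cfg, out, seed, record
        )

        stage = "detect"
        ddir = out / "detect"
        ddir.mkdir(exist_ok=True)
        params = DetectionParams()
        arrays = []
        for fasta in assemblies:
            arrays.extend(strain_scan(str(fasta), params, strain_id=Path(fasta).stem))
        cio.write_tsv(arrays_to_table(arrays), ddir / "arrays.tsv")
        cio.write_fasta(spacer_fasta_records(arrays), ddir / "spacers.fasta")
        record(stage, ddir / "arrays.tsv")
        log.info("detect: %d arrays", len(arrays))

        stage = "type"
        catalog = (
            RepeatCatalog.from_tsv(cfg["catalog"]) if cfg.get("catalog") else RepeatCatalog.default()
        )
        assign_types(arrays, catalog)

        stage = "context"
        for fasta, gff in zip(assemblies, gffs):
            strain = Path(fasta).stem
            cas = read_cas_genes(gff)
            classify_contexts([a for a in arrays if a.strain_id == strain], cas)
        tdir = out / "type"
        tdir.mkdir(exist_ok=True)
        cio.write_tsv(arrays_to_table(arrays), tdir / "arrays.typed.tsv")
        cio.write_tsv(tetraloop_census(arrays), tdir / "tetraloop_census.tsv")
        record("type", tdir / "arrays.typed.tsv")

        stage = "read-spacers"
        groups = []
        if reads_r1 and reads_r2:
            rdir = out / "read_spacers"
            rdir.mkdir(exist_ok=True)
            r1 = list(cio.read_fastq(reads_r1))
            r2 = list(cio.read_fastq(reads_r2))
            if host_fasta:
                pairs = [(a[0], a[1], b[1]) for a, b in zip(r1, r2)]
                kept = host_filter(pairs, cio.read_fasta(host_fasta))
                log.info("host filter kept %d/%d pairs", len(kept), len(pairs))
                r1 = [(p, s) for p, s, _ in kept]
                r2 = [(p, s) for p, _, s in kept]
            rp = ReadMinerParams()
            groups = extract_read_spacers(r1, rp, "R1") + extract_read_spacers(r2, rp, "R2")
            known = sorted({a.consensus_repeat for a in arrays})
            if known:
                groups += rescue_known_repeats(r1, known, rp, "R1")
                groups += rescue_known_repeats(r2, known, rp, "R2")
            groups = merge_groups(groups)
            rows = [
                {
                    "sample_id": g.sample_id,
                    "consensus_repeat": g.consensus_repeat,
                    "n_repeat_instances": g.n_repeat_instances,
                    "n_spacers": len(g.spacers),
                }
                for g in groups
            ]
            cio.write_tsv(pd.DataFrame(rows), rdir / "read_groups.tsv")
            record(stage, rdir / "read_groups.tsv")
        else:
            log.warning("read-spacers: no paired reads configured; stage skipped")

        stage = "match"
        mdir = out / "match"
        mdir.mkdir(exist_ok=True)
        reference: dict[str, str] = {}
        for fasta in assemblies:
            reference.update(cio.read_fasta(fasta))
        spacers = spacers_from_arrays(arrays)
        min_identity = float(cfg.get("min_identity", "0.80"))
        matches = match_spacers_to_reference(spacers, reference, min_identity=min_identity)
        cio.write_tsv(matches_to_table(matches), mdir / "matches.tsv")
        per_strain: dict[str, list] = {}
        for sp in spacers:
            per_strain.setdefault(sp.strain_id, []).append(sp)
        if len(per_strain) >= 2:
            summary = sharing_matrix(per_strain, min_identity=min_identity)
            summary.counts.to_csv(mdir / "sharing_matrix.tsv", sep="\t")
            cio.write_tsv(summary.to_edge_list(), mdir / "sharing_edges.tsv")
        record(stage, mdir / "matches.tsv")
        log.info("match: %d placements", len(matches))

        stage = "overlap"
        if prophage_bed:
            odir = out / "overlap"
            odir.mkdir(exist_ok=True)
            bed = cio.read_prophage_bed(prophage_bed)
            contig_to_strain = {c: c.rsplit("_", 1)[0] for c in bed["contig_id"].unique()}
            regions = regions_from_bed(bed, contig_to_strain)
            array_iv = [(a.contig_id, a.start, a.end) for a in arrays]
            gene_iv = []
            for gff in gffs:
                gene_iv.extend(
                    (f.contig_id, f.start, f.end) for f in cio.read_gff(gff, ftype="gene")
                )
            contig_lengths = {cid: len(seq) for cid, seq in reference.items()}
            result = attribute_matches(
                matches, regions, array_iv, gene_iv,
                pad=int(cfg.get("pad", "32")), contig_lengths=contig_lengths,
            )
            edges = edge_table(result)
            export_edges(edges, odir)
            cio.write_tsv(result.region_counts, odir / "region_counts.tsv")
            summary = pd.Series(genic_summary(result)).rename("count")
            cio.write_tsv(summary.to_frame().reset_index(names="tally"), odir / "genic_summary.tsv")
            record(stage, odir / "region_counts.tsv")
        else:
            log.warning("overlap: no prophage BED configured; stage skipped")

        stage = "stats"
        sdir = out / "stats"
        sdir.mkdir(exist_ok=True)
        cio.write_tsv(array_size_summary(arrays), sdir / "array_sizes.tsv")
        power_rows = []
        for i, text in enumerate(filter(None, cfg.get("power", "").split(";"))):
            from .cli import _split_power_spec

            parts = _split_power_spec(text)
            spec = PowerSpec(
                n1=int(parts[0]), n2=int(parts[1]),
                dist1=DistributionSpec.parse(parts[2]),
                dist2=DistributionSpec.parse(parts[3]),
                alpha=float(parts[4]) if len(parts) > 4 else 0.05,
                seed=seed + i,
            )
            power_rows.append({"n1": spec.n1, "n2": spec.n2, "power": wmw_power(spec)})
        if power_rows:
            cio.write_tsv(pd.DataFrame(power_rows), sdir / "power.tsv")
        record(stage, sdir / "array_sizes.tsv")
    except Exception as exc:
        pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def _stage_simulate(cfg, out, seed, record):
    if cfg.get("simulate", "").lower() in ("1", "true", "yes"):
        sdir = out / "sim"
        plans = demo_panel_plans(int(cfg.get("n_strains", "6")), seed=seed)
        panel = build_strain_panel(plans, seed=seed + 1)
        panel.write(sdir)
        strains = sorted(panel.assemblies)[:3]
        community = [(s, panel.assemblies[s], 1.0 / len(strains)) for s in strains]
        host = make_host_genome(20000, [panel.assemblies[s] for s in strains], seed=seed + 2)
        genome_bp = sum(len(c) for s in strains for c in panel.assemblies[s].values())
        pairs, _ = simulate_reads(
            community, host, host_fraction=0.3, read_len=150,
            n_pairs=int(20 * genome_bp / 300 / 0.7), error_rate=0.0, seed=seed + 3,
        )
        r1, r2 = write_paired_fastq(pairs, sdir / "sample1")
        cio.write_fasta({"host": host}, sdir / "host.fasta")
        record("simulate", sdir / "prophages.bed")
        assemblies = [sdir / f"{s}.fasta" for s in sorted(panel.assemblies)]
        gffs = [sdir / f"{s}.gff3" for s in sorted(panel.assemblies)]
        return assemblies, gffs, sdir / "prophages.bed", r1, r2, sdir / "host.fasta"
    assemblies = [Path(p) for p in cfg.get("assemblies", "").split(",") if p]
    gffs = [Path(p) for p in cfg.get("gffs", "").split(",") if p]
    if not assemblies:
        raise ValueError("config must set assemblies or simulate = true")
    if len(gffs) != len(assemblies):
        raise ValueError("gffs must align one-to-one with assemblies")
    get = lambda k: Path(cfg[k]) if cfg.get(k) else None  # noqa: E731
    return assemblies, gffs, get("prophage_bed"), get("reads_r1"), get("reads_r2"), get("host_fasta")
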