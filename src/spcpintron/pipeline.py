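"""Pipeline orchestration and command-line interface.

``run_all`` drives the full analysis — intron detection from
genomic/cDNA pairs, junction consensus, intron orthology, proto-splice
scanning of intronless taxa, distance and dN/dS statistics, parsimony
tree search and gain/loss accounting — and writes per-stage TSV/GFF3
outputs plus a versioned JSON summary.  The ``spcpintron`` console
script exposes each stage as a subcommand so stages can be rerun
standalone on the previous stage's outputs.

Exit codes: 0 ok, 1 user error (bad input/config), 2 internal error.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import yaml

from . import evodist, introncall, protosplice, simdata
from .phylo import CharacterMatrix, Tree, gain_loss_accounting, mp_search
from .seqio import (
    CodingAnnotation,
    SequenceRecord,
    load_annotations,
    read_fasta,
)

REPORT_SCHEMA_VERSION = "1.0"

logger = logging.getLogger("spcpintron")


def _setup_logging(logfile: Path | None = None) -> None:
    logger.setLevel(logging.DEBUG)
    logger.handlers.clear()
    sh = logging.StreamHandler(sys.stderr)
    sh.setLevel(logging.INFO)
    sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setLevel(logging.DEBUG)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one full run."""

    genomic: Path
    cdna: Path
    outdir: Path
    proteins: Path | None = None
    tree: Path | None = None
    annotations: Path | None = None
    outgroup: list[str] = field(default_factory=list)
    model: str = "K80"
    alpha: float | None = None
    min_intron_len: int = 50
    identity_threshold: float = 0.5
    junction_mismatch_max: int = 1
    co_loss: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = Path(path).parent
        kwargs = {}
        for key, value in doc.items():
            if key in ("genomic", "cdna", "proteins", "tree", "annotations", "outdir"):
                kwargs[key] = (base / value).resolve() if value else None
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        for key in ("genomic", "cdna"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {key} path does not exist: {p}")
        if not (0 < cfg.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if cfg.min_intron_len < 1:
            raise ValueError("min_intron_len must be >= 1")
        return cfg

    def params(self) -> introncall.IntronCallParams:
        return introncall.IntronCallParams(
            min_intron_len=self.min_intron_len,
            identity_threshold=self.identity_threshold,
            junction_mismatch_max=self.junction_mismatch_max,
        )


# ---------------------------------------------------------------------------
# Stage functions (library API; CLI subcommands are thin wrappers)


def detect_stage(
    genomic: list[SequenceRecord],
    cdna: list[SequenceRecord],
    annotations: dict[str, CodingAnnotation] | None = None,
    params: introncall.IntronCallParams | None = None,
) -> dict[str, introncall.CallResult]:
    """Call introns for every genomic/cDNA pair (matched by record id)."""
    cdna_by_id = {r.id: r for r in cdna}
    out: dict[str, introncall.CallResult] = {}
    for g in genomic:
        if g.id not in cdna_by_id:
            raise ValueError(f"detect: no cDNA record for {g.id!r}")
        ann = (annotations or {}).get(g.id) or CodingAnnotation(
            0, len(cdna_by_id[g.id].residues)
        )
        aln = introncall.align_pair(g, cdna_by_id[g.id], params)
        out[g.id] = introncall.call_introns(aln, ann, params)
        logger.info(
            "detect: %s -> %d introns, %d short indels",
            g.id, len(out[g.id].introns), len(out[g.id].indels),
        )
    return out


def introns_to_tsv(calls: dict[str, introncall.CallResult], path: Path) -> None:
    """1-based inclusive coordinates, per the reporting convention."""
    rows = [
        "taxon\tstart\tend\tlength\tphase\tdonor\tacceptor\t"
        "cds_insert_pos\thost_codon\twarning"
    ]
    for taxon, res in calls.items():
        for ic in res.introns:
            rows.append(
                f"{taxon}\t{ic.genomic_start + 1}\t{ic.genomic_end}\t"
                f"{ic.length}\t{ic.phase}\t{ic.donor.render()}\t"
                f"{ic.acceptor.render()}\t{ic.cds_insert_pos}\t"
                f"{ic.host_codon_index + 1}\t{int(ic.warning)}"
            )
    path.write_text("\n".join(rows) + "\n")


def introns_to_gff3(calls: dict[str, introncall.CallResult], path: Path) -> None:
    rows = ["##gff-version 3"]
    for taxon, res in calls.items():
        for i, ic in enumerate(res.introns, 1):
            rows.append(
                f"{taxon}\tspcpintron\tintron\t{ic.genomic_start + 1}\t"
                f"{ic.genomic_end}\t{ic.consensus_score}\t+\t.\t"
                f"ID=intron_{taxon}_{i};phase_class={ic.phase}"
            )
    path.write_text("\n".join(rows) + "\n")


def orthology_stage(
    calls: dict[str, introncall.CallResult],
    cds_alignment: dict[str, str],
    params: introncall.IntronCallParams | None = None,
) -> tuple[list[dict], list[list[tuple[str, int]]]]:
    """All-vs-all orthology across taxa; also groups introns into
    orthology classes (connected components of orthologous pairs)."""
    items = [
        (taxon, i, ic)
        for taxon, res in calls.items()
        for i, ic in enumerate(res.introns)
    ]
    pairs = []
    parent = {(t, i): (t, i) for t, i, _ in items}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (ta, ia, ca), (tb, ib, cb) in itertools.combinations(items, 2):
        if ta == tb:
            continue
        oc = introncall.call_orthology(ca, cb, cds_alignment, params)
        pairs.append(
            {
                "a": f"{ta}:{ia}", "b": f"{tb}:{ib}",
                "same_position": oc.same_position,
                "junction_compatible": oc.junction_compatible,
                "intron_identity": round(oc.intron_identity, 4),
                "orthologous": oc.orthologous,
            }
        )
        if oc.orthologous:
            parent[find((ta, ia))] = find((tb, ib))
    groups: dict[tuple, list[tuple[str, int]]] = {}
    for t, i, _ in items:
        groups.setdefault(find((t, i)), []).append((t, i))
    return pairs, sorted(groups.values(), key=lambda g: sorted(g))


def presence_matrix(
    groups: list[list[tuple[str, int]]], taxa: list[str]
) -> CharacterMatrix:
    """Intron orthology groups -> taxon x intron presence/absence matrix."""
    chars = [f"introngrp{i}" for i in range(len(groups))]
    states = {
        t: ["1" if any(t == gt for gt, _ in grp) else "0" for grp in groups]
        for t in taxa
    }
    return CharacterMatrix(taxa, chars, states)


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    stage = "load"
    try:
        genomic = read_fasta(config.genomic)
        cdna = read_fasta(config.cdna)
        if not cdna:
            raise ValueError(f"empty cdna file {config.cdna}")
        annotations = (
            load_annotations(config.annotations) if config.annotations else None
        )
        params = config.params()
        report: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "parameters": {
                "model": config.model,
                "alpha": config.alpha,
                "min_intron_len": config.min_intron_len,
                "identity_threshold": config.identity_threshold,
                "junction_mismatch_max": config.junction_mismatch_max,
                "co_loss": config.co_loss,
                "seed": config.seed,
            },
        }

        stage = "detect"
        calls = detect_stage(genomic, cdna, annotations, params)
        introns_to_tsv(calls, outdir / "introns.tsv")
        introns_to_gff3(calls, outdir / "introns.gff3")
        report["introns"] = {
            taxon: [
                {
                    "start_1based": ic.genomic_start + 1,
                    "end_1based": ic.genomic_end,
                    "length": ic.length,
                    "phase": ic.phase,
                    "donor": ic.donor.render(),
                    "acceptor": ic.acceptor.render(),
                    "cds_insert_pos": ic.cds_insert_pos,
                }
                for ic in res.introns
            ]
            for taxon, res in calls.items()
        }

        stage = "consensus"
        windows = [
            w
            for res in calls.values()
            for ic in res.introns
            for w in (ic.donor, ic.acceptor)
        ]
        if windows:
            donor, acceptor = introncall.junction_consensus(windows)
            report["junction_consensus"] = {"donor": donor, "acceptor": acceptor}

        stage = "orthology"
        msa = introncall.star_msa(cdna)
        pairs, groups = orthology_stage(calls, msa, params)
        report["orthology"] = {
            "pairs": pairs,
            "groups": [[f"{t}:{i}" for t, i in grp] for grp in groups],
        }

        stage = "protoscan"
        columns: dict[int, set[str]] = {}
        for taxon, res in calls.items():
            for ic in res.introns:
                col = introncall._insertion_column(msa[taxon], ic.cds_insert_pos)
                columns.setdefault(col, set()).add(taxon)
        observed = {
            protosplice.extract_fourmer(
                cdna_rec, ic.cds_insert_pos
            )
            for cdna_rec, res in (
                (next(r for r in cdna if r.id == t), res)
                for t, res in calls.items()
            )
            for ic in res.introns
            if ic.cds_insert_pos >= 3
        }
        hits = protosplice.scan_intronless(msa, columns, observed,
                                           protosplice.load_motif_list())
        report["protosplice"] = [
            {
                "taxon": h.taxon, "column": h.aln_column,
                "fourmer": h.fourmer, "class": h.match_class,
            }
            for h in hits
        ]

        stage = "dist"
        aligned = [
            SequenceRecord(t, msa[t], moltype="dna") for t in sorted(msa)
        ]
        dres = evodist.average_distance(
            aligned, model=config.model, alpha=config.alpha
        )
        sims = [
            evodist.global_percent_similarity(a.residues, b.residues)
            for a, b in itertools.combinations(genomic, 2)
        ]
        report["distances"] = {
            "model": dres.model,
            "average": dres.average,
            "mean_cassette_percent_similarity": (
                sum(sims) / len(sims) if sims else None
            ),
        }

        stage = "dnds"
        ratios = []
        for a, b in itertools.combinations(aligned, 2):
            res = evodist.nei_gojobori_dnds(a.residues, b.residues)
            if res.ratio is not None:
                ratios.append(res.ratio)
        report["dnds"] = {
            "n_pairs": len(ratios),
            "mean_ratio": sum(ratios) / len(ratios) if ratios else None,
        }

        stage = "tree"
        if config.tree is not None:
            tree = Tree.from_newick(Path(config.tree).read_text())
        elif len(aligned) >= 4:
            matrix = CharacterMatrix.from_alignment(aligned)
            best, score = mp_search(matrix, n_replicates=5, seed=config.seed)
            tree = best[0]
            (outdir / "mp_tree.nwk").write_text(tree.to_newick() + "\n")
            report["tree"] = {"mp_score": score, "newick": tree.to_newick()}
        else:
            tree = None

        stage = "gainloss"
        if tree is not None and groups:
            if not tree.is_rooted and config.outgroup:
                tree = tree.root_on_outgroup(set(config.outgroup))
            if tree.is_rooted:
                pmat = presence_matrix(groups, tree.tip_labels())
                gl = gain_loss_accounting(tree, pmat, co_loss=config.co_loss)
                report["gain_loss"] = {
                    "min_gains": gl.min_gains,
                    "forced_presence_single_losses":
                        gl.forced_presence_single_losses,
                    "forced_presence_event_losses":
                        gl.forced_presence_event_losses,
                }

        stage = "report"
        report = make_report(report)
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        logger.info("run-all: report written to %s", outdir / "report.json")
        return report
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


_SECTIONS = (
    "introns", "junction_consensus", "orthology", "protosplice",
    "distances", "dnds", "tree", "gain_loss",
)


def make_report(stage_outputs: dict) -> dict:
    """Assemble the final report; absent stages are marked explicitly."""
    report = dict(stage_outputs)
    report.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    report["sections_missing"] = [s for s in _SECTIONS if s not in report]
    return report


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli() -> None:
    """Intron discovery, orthology and gain/loss dating for sPCP genes."""
    _setup_logging()


@cli.command("run-all")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def cli_run_all(config_path: str) -> None:
    """Run every stage from a YAML run configuration."""
    try:
        config = RunConfig.from_yaml(config_path)
    except (ValueError, FileNotFoundError, KeyError, TypeError) as exc:
        raise click.ClickException(str(exc))
    try:
        run_all(config)
    except RuntimeError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(2)


@cli.command()
@click.option("--genomic", required=True, type=click.Path(exists=True))
@click.option("--cdna", required=True, type=click.Path(exists=True))
@click.option("--annotations", type=click.Path(exists=True))
@click.option("--min-intron-len", default=50, show_default=True)
@click.option("--out", required=True, type=click.Path())
def detect(genomic, cdna, annotations, min_intron_len, out):
    """Detect introns from paired genomic and cDNA FASTA files."""
    params = introncall.IntronCallParams(min_intron_len=min_intron_len)
    anns = load_annotations(annotations) if annotations else None
    calls = detect_stage(read_fasta(genomic), read_fasta(cdna), anns, params)
    introns_to_tsv(calls, Path(out))
    click.echo(f"wrote {out}")


@cli.command()
@click.option("--genomic", required=True, type=click.Path(exists=True))
@click.option("--cdna", required=True, type=click.Path(exists=True))
@click.option("--alignment", type=click.Path(exists=True),
              help="Aligned CDS FASTA (default: star alignment of the cDNAs)")
@click.option("--identity-threshold", default=0.5, show_default=True)
@click.option("--out", required=True, type=click.Path())
def orthology(genomic, cdna, alignment, identity_threshold, out):
    """All-vs-all intron orthology calls across taxa."""
    params = introncall.IntronCallParams(identity_threshold=identity_threshold)
    cdna_recs = read_fasta(cdna)
    calls = detect_stage(read_fasta(genomic), cdna_recs, None, params)
    if alignment:
        msa = {r.id: r.residues for r in read_fasta(alignment)}
    else:
        msa = introncall.star_msa(cdna_recs)
    pairs, groups = orthology_stage(calls, msa, params)
    rows = ["a\tb\tsame_position\tjunction_compatible\tintron_identity\torthologous"]
    for p in pairs:
        rows.append(
            f"{p['a']}\t{p['b']}\t{int(p['same_position'])}\t"
            f"{int(p['junction_compatible'])}\t{p['intron_identity']}\t"
            f"{int(p['orthologous'])}"
        )
    Path(out).write_text("\n".join(rows) + "\n")
    click.echo(f"{len(groups)} orthology group(s); wrote {out}")


@cli.command()
@click.option("--alignment", required=True, type=click.Path(exists=True),
              help="Aligned CDS FASTA")
@click.option("--columns", "columns_path", required=True,
              type=click.Path(exists=True),
              help="TSV: column index, then comma-separated bearer taxa")
@click.option("--motifs", type=click.Path(exists=True),
              help="Cryptic-variant motif list (one 4-mer per line)")
@click.option("--out", required=True, type=click.Path())
def protoscan(alignment, columns_path, motifs, out):
    """Score potential exon junctions in intronless taxa."""
    msa = {r.id: r.residues for r in read_fasta(alignment)}
    columns: dict[int, set[str]] = {}
    for line in Path(columns_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        bearers = set(cells[1].split(",")) if len(cells) > 1 and cells[1] else set()
        columns[int(cells[0])] = bearers
    cryptic = protosplice.load_motif_list(motifs)
    hits = protosplice.scan_intronless(msa, columns, cryptic_list=cryptic)
    rows = ["taxon\tcolumn\tfourmer\tclass\tgapped"]
    for h in hits:
        rows.append(f"{h.taxon}\t{h.aln_column}\t{h.fourmer or '-'}\t"
                    f"{h.match_class}\t{int(h.gapped)}")
    Path(out).write_text("\n".join(rows) + "\n")
    click.echo(f"wrote {out}")


@cli.command()
@click.option("--alignment", required=True, type=click.Path(exists=True),
              help="Aligned FASTA")
@click.option("--model", default="K80", show_default=True,
              type=click.Choice(["p", "F81", "K80", "HKY85", "K80G"]))
@click.option("--alpha", type=float, default=None,
              help="Gamma shape for K80G")
@click.option("--out", required=True, type=click.Path())
def dist(alignment, model, alpha, out):
    """Pairwise distance matrix and average under one model."""
    records = read_fasta(alignment)
    res = evodist.average_distance(records, model=model, alpha=alpha)
    df = res.as_dataframe()
    df.to_csv(out, sep="\t", float_format="%.6f")
    click.echo(f"model {model} average {res.average:.5f}; wrote {out}")


@cli.command()
@click.option("--alignment", required=True, type=click.Path(exists=True),
              help="Codon-aligned CDS FASTA")
@click.option("--out", required=True, type=click.Path())
def dnds(alignment, out):
    """Pairwise Nei-Gojobori dN/dS for aligned coding sequences."""
    records = read_fasta(alignment)
    rows = ["a\tb\tS\tN\tSd\tNd\tdS\tdN\tratio"]
    for a, b in itertools.combinations(records, 2):
        r = evodist.nei_gojobori_dnds(a.residues, b.residues)
        rows.append(
            f"{a.id}\t{b.id}\t{r.S_sites:.2f}\t{r.N_sites:.2f}\t{r.Sd:.2f}\t"
            f"{r.Nd:.2f}\t{_fmt(r.dS)}\t{_fmt(r.dN)}\t{_fmt(r.ratio)}"
        )
    Path(out).write_text("\n".join(rows) + "\n")
    click.echo(f"wrote {out}")


def _fmt(x) -> str:
    return "NA" if x is None else f"{x:.4f}"


@cli.command()
@click.option("--tree", "tree_path", required=True, type=click.Path(exists=True))
@click.option("--matrix", "matrix_path", required=True, type=click.Path(exists=True),
              help="TSV: taxon column then one 0/1/? column per intron")
@click.option("--root-on", multiple=True, help="Outgroup taxa for rooting")
@click.option("--co-loss/--no-co-loss", default=True, show_default=True)
def gainloss(tree_path, matrix_path, root_on, co_loss):
    """Gain/loss event accounting on a rooted tree."""
    tree = Tree.from_newick(Path(tree_path).read_text())
    matrix = _read_matrix_tsv(Path(matrix_path))
    if root_on:
        tree = tree.root_on_outgroup(set(root_on))
    res = gain_loss_accounting(tree, matrix, co_loss=co_loss)
    click.echo(json.dumps({
        "min_gains": res.min_gains,
        "forced_presence_single_losses": res.forced_presence_single_losses,
        "forced_presence_event_losses": res.forced_presence_event_losses,
    }, indent=2))


def _read_matrix_tsv(path: Path) -> CharacterMatrix:
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    header = lines[0].split("\t")
    chars = header[1:]
    taxa, states = [], {}
    for line in lines[1:]:
        cells = line.split("\t")
        taxa.append(cells[0])
        states[cells[0]] = cells[1:]
    return CharacterMatrix(taxa, chars, states)


@cli.command()
@click.option("--matrix", "matrix_path", required=True, type=click.Path(exists=True),
              help="Aligned FASTA to analyse under parsimony")
@click.option("--replicates", default=10, show_default=True)
@click.option("--boot", default=0, show_default=True,
              help="Bootstrap pseudo-replicates (0 = skip)")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def tree(matrix_path, replicates, boot, seed, out):
    """Heuristic most-parsimonious tree search (+ optional bootstrap)."""
    from .phylo import bootstrap_support

    records = read_fasta(matrix_path)
    matrix = CharacterMatrix.from_alignment(records)
    best, score = mp_search(matrix, n_replicates=replicates, seed=seed)
    text = "\n".join(t.to_newick() for t in best) + "\n"
    Path(out).write_text(text)
    click.echo(f"best score {score}; {len(best)} tree(s) -> {out}  # seed={seed}")
    if boot:
        support = bootstrap_support(matrix, best[0], n_boot=boot, seed=seed)
        for bp, pct in sorted(support.items(), key=lambda kv: -kv[1]):
            click.echo(f"{pct:5.1f}%  {{{','.join(sorted(bp))}}}")


@cli.command()
@click.option("--proteins", required=True, type=click.Path(exists=True))
@click.option("--short", "short_id", required=True)
@click.option("--long", "long_id", required=True)
@click.option("--window", default=16, show_default=True)
@click.option("--stringency", default=40.0, show_default=True)
def dotplot(proteins, short_id, long_id, window, stringency):
    """Short-vs-long domain comparison for two protein records."""
    from .domains import compare_short_to_long

    records = {r.id: r for r in read_fasta(proteins, moltype="protein")}
    res = compare_short_to_long(
        records[short_id], records[long_id], window=window, stringency=stringency
    )
    click.echo(json.dumps(res, indent=2))


@cli.command()
@click.option("--kind", default="long", show_default=True,
              type=click.Choice(["long", "short"]))
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", required=True, type=click.Path())
def simulate(kind, seed, outdir):
    """Emit a synthetic cassette dataset with ground truth."""
    cfg = (
        simdata.default_long_config(seed)
        if kind == "long"
        else simdata.default_short_config(seed)
    )
    ds = simdata.emit_dataset(cfg)
    ds.write(outdir)
    click.echo(f"wrote {outdir} (seed={seed}, taxa={len(ds.genomic)})")


@cli.command()
@click.option("--clones", required=True, type=click.Path(exists=True))
@click.option("--references", required=True, type=click.Path(exists=True))
@click.option("--threshold", default=0.04, show_default=True)
def chimera(clones, references, threshold):
    """Breakpoint chimera screen of aligned clones against references."""
    calls = evodist.chimera_screen(
        read_fasta(clones), read_fasta(references), threshold=threshold
    )
    for c in calls:
        flag = f"CHIMERIC bp={c.breakpoint} parents={c.parents}" if c.chimeric \
            else "ok"
        click.echo(f"{c.clone}\t{flag}")


def main() -> None:  # pragma: no cover
    cli()
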