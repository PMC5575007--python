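"""End-to-end cohort runs: scan -> seeds -> architecture -> report.

``run_cohort`` applies the refined motif scan to a sequence cohort,
optionally overlays seed complementarity against target mRNAs and
structural context from dot-bracket files, and writes a reproducible
bundle: per-sequence region TSV/BED, a regions-per-sequence histogram
(bins 0, 1, 2, 3, 4, 5+), a machine-readable JSON summary and an echo
of the exact configuration that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .architecture import motif_context, poly_u_distance
from .motif_search import ScanParams, ScanReport, scan_set
from .seed_finder import SeedParams, find_seeds
from .seqio import read_dotbracket, read_fasta, write_regions

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "run_cohort"]


@dataclass
class RunConfig:
    """Everything a cohort run depends on; serialized alongside outputs."""

    fasta: str
    out_dir: str
    mrna_fasta: Optional[str] = None
    structure_file: Optional[str] = None
    n_arn_min: int = 4
    window_nt: int = 20
    max_nf: int = 2
    max_gaps: int = 2
    allow_wobble: bool = False
    min_u_run: int = 4
    u_search_window: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def scan_params(self) -> ScanParams:
        return ScanParams(
            n_arn_min=self.n_arn_min,
            max_nf=self.max_nf,
            max_gaps=self.max_gaps,
            window_nt=self.window_nt,
        )


def run_cohort(config: RunConfig) -> dict:
    """Run the full pipeline per ``config`` and write the report bundle.

    Returns the JSON summary as a dict.  Any stage failure raises with a
    stage-named message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        seqs = read_fasta(config.fasta)
    except Exception as exc:
        raise RuntimeError(f"[input] {exc}") from exc
    if not seqs:
        raise RuntimeError("[input] no sequences")

    try:
        report: ScanReport = scan_set(seqs, config.scan_params())
    except Exception as exc:
        raise RuntimeError(f"[scan] {exc}") from exc

    all_regions = [r for regs in report.regions.values() for r in regs]
    write_regions(all_regions, out / "regions.tsv", "tsv")
    write_regions(all_regions, out / "regions.bed", "bed")
    (out / "scan_report.tsv").write_text(report.to_tsv())

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "arnscan_version": __version__,
        "config": asdict(config),
        "n_sequences": len(seqs),
        "n_with_motif": report.n_with_motif,
        "histogram": report.histogram,
        "regions": {
            sid: [[r.interval.start, r.interval.end, r.max_arn] for r in regs]
            for sid, regs in report.regions.items()
        },
    }

    if config.mrna_fasta:
        try:
            mrnas = read_fasta(config.mrna_fasta)
            seed_rows = []
            sparams = SeedParams(allow_wobble=config.allow_wobble)
            for srna in seqs:
                for mrna in mrnas:
                    for sm in find_seeds(srna, mrna, sparams):
                        seed_rows.append(
                            "\t".join(
                                map(
                                    str,
                                    (
                                        sm.srna_interval.seq_id,
                                        sm.srna_interval.start,
                                        sm.srna_interval.end,
                                        sm.mrna_interval.seq_id,
                                        sm.mrna_interval.start,
                                        sm.mrna_interval.end,
                                        sm.kind.value,
                                        sm.gap_strand.value,
                                        sm.pair_string,
                                    ),
                                )
                            )
                        )
            header = (
                "srna_id\tsrna_start\tsrna_end\tmrna_id\tmrna_start\tmrna_end"
                "\tkind\tgap_strand\tpair_string"
            )
            (out / "seeds.tsv").write_text(
                "\n".join([header] + seed_rows) + "\n"
            )
            summary["n_seed_matches"] = len(seed_rows)
        except Exception as exc:
            raise RuntimeError(f"[seeds] {exc}") from exc

    if config.structure_file:
        try:
            structures = {
                st.seq_id: st for st in read_dotbracket(config.structure_file)
            }
            arch_rows = []
            by_id = {s.id: s for s in seqs}
            for sid, regs in report.regions.items():
                st = structures.get(sid)
                for reg in regs:
                    ctx = (
                        motif_context(reg.interval, st, offset=by_id[sid].offset)
                        if st is not None and len(st) == len(by_id[sid])
                        else None
                    )
                    dist = poly_u_distance(
                        by_id[sid],
                        reg.interval,
                        min_u_run=config.min_u_run,
                        search_window=config.u_search_window,
                    )
                    arch_rows.append(
                        "\t".join(
                            map(
                                str,
                                (
                                    sid,
                                    reg.interval.start,
                                    reg.interval.end,
                                    ctx.embraced if ctx else "NA",
                                    f"{ctx.unpaired_fraction:.3f}" if ctx else "NA",
                                    dist if dist is not None else "NA",
                                ),
                            )
                        )
                    )
            header = "seq_id\tstart\tend\tembraced\tunpaired_fraction\tpoly_u_distance"
            (out / "architecture.tsv").write_text(
                "\n".join([header] + arch_rows) + "\n"
            )
            summary["n_architecture_rows"] = len(arch_rows)
        except Exception as exc:
            raise RuntimeError(f"[architecture] {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    logger.info(
        "scanned %d sequences, %d with >=1 motif region",
        len(seqs),
        report.n_with_motif,
    )
    return summary
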