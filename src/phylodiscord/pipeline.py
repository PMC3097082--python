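"""End-to-end orchestration: conflicts -> ploidy flagging -> optional ASR.

`run_pipeline` is a plain library function (the package has no command-line
interface); it returns the report bundle as a dict and, when an output
directory is given, writes the same content as deterministic JSON and TSV
files plus a human-readable summary.  Identical config + inputs produce
byte-identical outputs (no timestamps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .conflicts import cluster_events, find_conflicting_pairs
from .errors import ValidationError
from .mk import CharacterMatrix, fit_model, likelihood_ratio_test, marginal_asr
from .ploidy import flag_events, read_ploidy_table
from .trees import Tree, read_trees, resolve_polytomies

__all__ = ["RunConfig", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Tree/table inputs may be given as paths or as in-memory objects.
    """

    nuclear_tree: object
    chloroplast_tree: object
    ploidy_table: object = None
    thr1: float = 0.95
    thr2: float = 0.95
    include_uncertain_ploidy: bool = True
    asr_characters: dict = field(default_factory=dict)  # name -> CharacterMatrix
    asr_models: tuple = ("ER", "SYM", "ARD")
    asr_tree: str = "nuclear"  # which tree carries the reconstruction
    seed: int = 0
    out_dir: object = None

    def __post_init__(self):
        for thr in (self.thr1, self.thr2):
            if not 0.0 <= thr <= 1.0:
                raise ValidationError(f"threshold {thr} outside [0, 1]")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")


def _load_tree(source) -> Tree:
    if isinstance(source, Tree):
        return source
    trees = read_trees(source)
    if len(trees) != 1:
        raise ValidationError(f"{source} holds {len(trees)} trees, expected 1")
    return trees[0]


def _event_record(event) -> dict:
    return {
        "label": event.label,
        "rogue_clade": sorted(event.rogue_clade),
        "involved_taxa": sorted(event.involved_taxa),
        "n_attributed_pairs": len(event.attributed_pairs),
        "attributed_pairs": [
            {
                "nuclear_clade": sorted(p.split_1.clade_side or p.split_1.side_a),
                "nuclear_support": p.split_1.support,
                "chloroplast_clade": sorted(p.split_2.clade_side or p.split_2.side_a),
                "chloroplast_support": p.split_2.support,
            }
            for p in event.attributed_pairs
        ],
        "allopolyploid_candidate": event.allopolyploid_candidate,
        "polyploid_evidence": [
            {"taxon": taxon, "levels": levels} for taxon, levels in event.evidence
        ],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the report bundle."""
    nuclear = _load_tree(config.nuclear_tree)
    chloroplast = _load_tree(config.chloroplast_tree)

    pairs = find_conflicting_pairs(nuclear, chloroplast, config.thr1, config.thr2)
    events = cluster_events(pairs, nuclear, chloroplast)

    missing = []
    if config.ploidy_table is not None:
        records = (
            config.ploidy_table
            if isinstance(config.ploidy_table, list)
            else read_ploidy_table(config.ploidy_table)
        )
        events, missing = flag_events(
            events, records, include_uncertain=config.include_uncertain_ploidy
        )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "parameters": {
            "thr1": config.thr1,
            "thr2": config.thr2,
            "include_uncertain_ploidy": config.include_uncertain_ploidy,
            "seed": config.seed,
        },
        "n_conflict_pairs": len(pairs),
        "n_events": len(events),
        "n_flagged": sum(1 for e in events if e.allopolyploid_candidate),
        "events": [_event_record(e) for e in events],
        "taxa_without_ploidy_record": missing,
    }

    if config.asr_characters:
        asr_base = nuclear if config.asr_tree == "nuclear" else chloroplast
        binary = resolve_polytomies(asr_base)
        report["asr"] = {}
        for name, chars in config.asr_characters.items():
            if not isinstance(chars, CharacterMatrix):
                raise ValidationError(f"asr character {name!r} must be a CharacterMatrix")
            present = {t: chars.data[t] for t in binary.leaves}
            chars = CharacterMatrix(present, chars.alphabet, names=chars.names)
            fits = {
                kind: fit_model(binary, chars, kind) for kind in config.asr_models
            }
            lrts = []
            order = [k for k in ("ER", "SYM", "ARD") if k in fits]
            best = order[0]
            for i in range(len(order) - 1):
                lrt = likelihood_ratio_test(fits[order[i]], fits[order[i + 1]])
                lrts.append(
                    {
                        "nested": lrt.nested_kind,
                        "general": lrt.general_kind,
                        "statistic": round(lrt.statistic, 6),
                        "df": lrt.df,
                        "p": lrt.p,
                    }
                )
                # step up only where the richer model is justified
                if lrt.p < 0.05 and best == lrt.nested_kind:
                    best = lrt.general_kind
            asr = marginal_asr(binary, chars, fits[best].model)
            report["asr"][name] = {
                "alphabet": list(chars.alphabet),
                "fits": {
                    kind: {
                        "log_likelihood": fits[kind].log_likelihood,
                        "rates": [float(r) for r in fits[kind].model.params],
                        "converged": fits[kind].converged,
                    }
                    for kind in order
                },
                "lrt": lrts,
                "best_model": best,
                "node_scaled_likelihoods": {
                    ";".join(sorted(clade)): [float(x) for x in vec[0]]
                    for clade, vec in sorted(
                        asr.node_likelihoods.items(), key=lambda kv: sorted(kv[0])
                    )
                },
            }

    if config.out_dir is not None:
        _write_reports(report, Path(config.out_dir))
    return report


def _write_reports(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp_paths = []
    try:
        json_path = out_dir / "report.json"
        json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        tmp_paths.append(json_path)
        tsv_path = out_dir / "events.tsv"
        with open(tsv_path, "w") as fh:
            fh.write(
                "label\trogue_clade\tinvolved_taxa\tn_pairs\t"
                "allopolyploid_candidate\tpolyploid_evidence\n"
            )
            for ev in report["events"]:
                evidence = ",".join(
                    f"{e['taxon']}:{'/'.join(str(x) + 'x' for x in e['levels'])}"
                    for e in ev["polyploid_evidence"]
                )
                fh.write(
                    f"{ev['label']}\t{','.join(ev['rogue_clade'])}\t"
                    f"{','.join(ev['involved_taxa'])}\t{ev['n_attributed_pairs']}\t"
                    f"{ev['allopolyploid_candidate']}\t{evidence}\n"
                )
        tmp_paths.append(tsv_path)
        summary = out_dir / "summary.txt"
        lines = [
            f"phylodiscord report (schema v{report['schema_version']})",
            f"conflict pairs: {report['n_conflict_pairs']}",
            f"incongruence events: {report['n_events']}",
            f"allopolyploidy candidates: {report['n_flagged']}",
        ]
        for ev in report["events"]:
            flag = "FLAGGED" if ev["allopolyploid_candidate"] else "not flagged"
            lines.append(
                f"  {ev['label']} rogue={','.join(ev['rogue_clade'])} [{flag}]"
            )
        summary.write_text("\n".join(lines) + "\n")
    except Exception:
        for p in tmp_paths:
            p.unlink(missing_ok=True)
        raise
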