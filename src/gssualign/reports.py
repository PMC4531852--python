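"""Plain-text and JSON report rendering.

The pairwise text report lists, in order: the S-distance, the p-value
(when computed), the alignment quality measures (RMSD over phosphates,
PSI, PID, number of aligned nucleotides, number of exact base matches)
and the per-structure GSSU/nucleotide summary.  The multiple-alignment
report stacks one such section per member, ordered by descending
S-distance against the average structure.

JSON reports are rendered with sorted keys and fixed formatting so that
repeated runs with identical inputs are byte-identical.
"""

from __future__ import annotations

import json
from typing import Sequence

from .gssu import Gssu
from .multiple import MultiResult
from .structure_io import RnaStructure
from .superpose import AlignParams, PairResult


def _structure_block(s: RnaStructure, gssus: Sequence[Gssu]) -> dict:
    return {
        "id": s.id,
        "n_nucleotides": len(s),
        "n_gssus": len(gssus),
        "gssus": [
            {"index": g.index, "stem_bp": g.stem_len, "loop_nt": len(g.loop),
             "has_neck": g.neck is not None}
            for g in gssus
        ],
    }


def pairwise_report_dict(result: PairResult,
                         sa: RnaStructure, sb: RnaStructure,
                         gssus_a: Sequence[Gssu], gssus_b: Sequence[Gssu],
                         params: AlignParams) -> dict:
    return {
        "mode": "pairwise",
        "s_distance": result.s_distance,
        "p_value": result.p_value,
        "quality": result.quality.as_dict(),
        "best_gssu_pair": list(result.best_gssu_pair),
        "structures": [_structure_block(sa, gssus_a),
                       _structure_block(sb, gssus_b)],
        "params": {"nn_cutoff": params.nn_cutoff,
                   "max_iter": params.max_iter,
                   "min_stem": params.min_stem},
    }


def _quality_lines(result: PairResult) -> list[str]:
    q = result.quality
    lines = [f"S-distance:          {result.s_distance:.6f}"]
    if result.p_value is not None:
        lines.append(f"p-value:             {result.p_value:.6f}")
    lines += [
        f"RMSD (phosphates):   {q.rmsd_phosphate:.4f} A",
        f"PSI:                 {q.psi:.1f} %",
        f"PID:                 {q.pid:.1f} %",
        f"Aligned nucleotides: {q.n_aligned}",
        f"Exact base matches:  {q.n_exact}",
    ]
    return lines


def _gssu_table(blocks: Sequence[tuple[RnaStructure, Sequence[Gssu]]]) -> list[str]:
    lines = ["", "Structure            GSSUs  Nucleotides"]
    for s, gssus in blocks:
        lines.append(f"{s.id[:20]:<20} {len(gssus):>5}  {len(s):>11}")
    return lines


def pairwise_report_text(result: PairResult,
                         sa: RnaStructure, sb: RnaStructure,
                         gssus_a: Sequence[Gssu], gssus_b: Sequence[Gssu]) -> str:
    lines = [f"Pairwise alignment: {sa.id} vs {sb.id}", ""]
    lines += _quality_lines(result)
    lines += _gssu_table([(sa, gssus_a), (sb, gssus_b)])
    return "\n".join(lines) + "\n"


def multi_report_dict(result: MultiResult,
                      params: AlignParams) -> dict:
    return {
        "mode": "multi",
        "n_structures": len(result.per_member),
        "guide_tree_newick": result.tree.to_newick().strip(),
        "average_n_nucleotides": len(result.average.structure),
        "average_weight": result.average.weight,
        "members": [
            {"id": sid,
             "s_distance": res.s_distance,
             "quality": res.quality.as_dict(),
             "best_gssu_pair": list(res.best_gssu_pair)}
            for sid, res in result.per_member
        ],
        "params": {"nn_cutoff": params.nn_cutoff,
                   "max_iter": params.max_iter,
                   "min_stem": params.min_stem},
    }


def multi_report_text(result: MultiResult) -> str:
    lines = [f"Multiple alignment of {len(result.per_member)} structures",
             f"Average structure: {len(result.average.structure)} nucleotides "
             f"(weight {result.average.weight})",
             "",
             "Members vs average (descending S-distance):"]
    for sid, res in result.per_member:
        q = res.quality
        lines.append("")
        lines.append(f"  {sid}")
        lines.append(f"    S-distance: {res.s_distance:.6f}")
        lines.append(f"    RMSD {q.rmsd_phosphate:.4f} A | PSI {q.psi:.1f} % | "
                     f"PID {q.pid:.1f} % | aligned {q.n_aligned} | "
                     f"exact {q.n_exact}")
    return "\n".join(lines) + "\n"


def to_json(report: dict) -> str:
    """Deterministic JSON rendering (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
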