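"""Species-boundary classification from the computed genome metrics.

Verdict rules (inclusive on the same-species side, since failures are
conventionally phrased as falling *below* the identity cutoffs or *above*
the signature cutoff):

* ANI  >= 95%   -> same species
* AAI  >= 95%   -> same species
* DDH  >= 70%   -> same species
* delta <= 0.01 -> same species

The consensus is this package's own combiner (the individual metrics are
classically applied side by side): a pair is called same-species when
every *available* verdict among ANI/AAI/DDH says same-species and the
dinucleotide verdict, if available, does not say different.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import aaicalc, anicalc, ddhest, dinucsig, seqio

__all__ = ["CUTOFFS", "TaxonomyCall", "call_pair", "run_all"]

log = logging.getLogger("gentaxo")

CUTOFFS = {"ani": 95.0, "aai": 95.0, "ddh": 70.0, "delta": 0.01}

SAME, DIFFERENT, NO_SIGNAL = "same-species", "different", "no-signal"


@dataclass
class TaxonomyCall:
    genome_a: str
    genome_b: str
    metrics: dict[str, float | None]      # subset of ani/aai/ddh/delta/...
    verdicts: dict[str, str] = field(default_factory=dict)
    consensus: str = NO_SIGNAL

    def to_dict(self) -> dict:
        return {"genome_a": self.genome_a, "genome_b": self.genome_b,
                "metrics": self.metrics, "verdicts": self.verdicts,
                "consensus": self.consensus}


def _verdict(metric: str, value: float | None) -> str:
    if value is None:
        return NO_SIGNAL
    cut = CUTOFFS[metric]
    if metric == "delta":
        return SAME if value <= cut else DIFFERENT
    return SAME if value >= cut else DIFFERENT


def call_pair(genome_a: str, genome_b: str,
              metrics: dict[str, float | None]) -> TaxonomyCall:
    """Apply the cutoff rules to the available metrics of one pair.

    ``metrics`` may hold any subset of "ani", "aai", "ddh", "delta";
    other keys (e.g. marker identities) are carried through unjudged.
    """
    if not metrics:
        raise ValueError("at least one metric required")
    verdicts = {m: _verdict(m, v) for m, v in metrics.items() if m in CUTOFFS}
    informative = [v for v in verdicts.values() if v != NO_SIGNAL]
    if not informative:
        consensus = NO_SIGNAL
    else:
        identity_verdicts = [verdicts[m] for m in ("ani", "aai", "ddh")
                             if verdicts.get(m, NO_SIGNAL) != NO_SIGNAL]
        delta_v = verdicts.get("delta", NO_SIGNAL)
        if all(v == SAME for v in identity_verdicts) and delta_v != DIFFERENT:
            consensus = SAME
        else:
            consensus = DIFFERENT
    return TaxonomyCall(genome_a, genome_b, dict(metrics), verdicts, consensus)


def run_all(genomes: list[seqio.GenomeRecord],
            proteomes: dict[str, seqio.Proteome] | None = None,
            metrics: tuple[str, ...] = ("ani", "aai", "ddh", "dinuc"),
            ani_params: anicalc.AniParams = anicalc.AniParams(),
            aai_params: aaicalc.AaiParams = aaicalc.AaiParams(),
            ddh_model: ddhest.DdhModel = ddhest.DEFAULT_MODEL,
            out_dir: str | Path | None = None) -> dict:
    """Compute the requested metric matrices and a taxonomy call per pair.

    Per-pair failures are isolated: the failing metric is recorded as
    None and the run continues.  Returns a JSON-serializable report; with
    ``out_dir`` also writes per-metric TSV matrices, calls.tsv and
    report.json.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    labels = [g.genome_id for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome ids")
    want_aai = "aai" in metrics and proteomes is not None
    profiles = {}
    if "dinuc" in metrics:
        for g in genomes:
            try:
                profiles[g.genome_id] = dinucsig.dinuc_profile(g)
            except ValueError as exc:
                log.warning("dinucleotide profile failed for %s: %s", g.genome_id, exc)

    calls: list[TaxonomyCall] = []
    matrices: dict[str, dict[tuple[str, str], float | None]] = {
        m: {} for m in ("ani", "aai", "ddh", "delta")}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            a, b = genomes[i], genomes[j]
            vals: dict[str, float | None] = {}
            oneways = None
            if "ani" in metrics or "ddh" in metrics:
                try:  # one set of fragment alignments feeds both ANI and DDH
                    oneways = (anicalc.ani_oneway(a, b, ani_params),
                               anicalc.ani_oneway(b, a, ani_params))
                except Exception as exc:          # isolate per-pair failures
                    log.warning("fragment alignment failed for %s-%s: %s",
                                a.genome_id, b.genome_id, exc)
            if "ani" in metrics:
                if oneways is not None:
                    fwd, rev = oneways
                    means = [v for v in (fwd.mean_identity, rev.mean_identity)
                             if v is not None]
                    vals["ani"] = sum(means) / len(means) if means else None
                else:
                    vals["ani"] = None
            if want_aai:
                try:
                    vals["aai"] = aaicalc.aai(proteomes[a.genome_id],
                                              proteomes[b.genome_id], aai_params).aai
                except Exception as exc:
                    log.warning("AAI failed for %s-%s: %s", a.genome_id, b.genome_id, exc)
                    vals["aai"] = None
            if "ddh" in metrics:
                if oneways is not None:
                    gd = ddhest.distance_from_oneway(a.genome_id, b.genome_id,
                                                     *oneways)
                    est = ddhest.ddh_estimate(gd, ddh_model)
                    vals["ddh"] = None if est is None else est.predicted_ddh
                else:
                    vals["ddh"] = None
            if "dinuc" in metrics:
                pa, pb = profiles.get(a.genome_id), profiles.get(b.genome_id)
                vals["delta"] = (dinucsig.delta(pa, pb).delta
                                 if pa is not None and pb is not None else None)
            for m, v in vals.items():
                key = "delta" if m == "delta" else m
                matrices[key][(a.genome_id, b.genome_id)] = v
            calls.append(call_pair(a.genome_id, b.genome_id, vals))

    report = {
        "genomes": labels,
        "parameters": {
            "cutoffs": CUTOFFS,
            "ani": {"frag_len": ani_params.frag_len,
                    "min_identity": ani_params.min_identity,
                    "min_frag_cov": ani_params.min_frag_cov},
            "aai": {"max_evalue": aai_params.max_evalue,
                    "min_identity": aai_params.min_identity,
                    "min_cov": aai_params.min_cov},
            "ddh_model": {"alpha": ddh_model.alpha, "beta": ddh_model.beta},
        },
        "calls": [c.to_dict() for c in calls],
        "n_same_species_pairs": sum(1 for c in calls if c.consensus == SAME),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m, cells in matrices.items():
            if not cells:
                continue
            with open(out / f"{m}_matrix.tsv", "w") as fh:
                fh.write("genome_id\t" + "\t".join(labels) + "\n")
                for ga in labels:
                    row = [ga]
                    for gb in labels:
                        if ga == gb:
                            row.append("0" if m == "delta" else "100")
                        else:
                            v = cells.get((ga, gb), cells.get((gb, ga)))
                            row.append("NA" if v is None else f"{v:.4f}")
                    fh.write("\t".join(row) + "\n")
        with open(out / "calls.tsv", "w") as fh:
            fh.write("genome_a\tgenome_b\tani\taai\tddh\tdelta\tconsensus\n")
            for c in calls:
                cells = [c.metrics.get(k) for k in ("ani", "aai", "ddh", "delta")]
                fh.write(c.genome_a + "\t" + c.genome_b + "\t"
                         + "\t".join("NA" if v is None else f"{v:.4f}" for v in cells)
                         + "\t" + c.consensus + "\n")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
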