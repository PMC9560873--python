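"""End-to-end comparison pipeline: plastomes + tree + group labels in,
per-taxon trait matrix, phylogenetic tests and a rendered report out.

The eight-plus-one comparative variables are: dispersed repeat number,
tandem repeat number, rearrangement distance, indel frequency, SNV
frequency, whole-plastome GC, protein-coding GC, GC3, and synonymous rate
dS.  Group labels are IR_lacking / IR_present / CRCIR; the two-group
phylogenetic t-test contrasts IR_lacking (coded 0) against CRCIR (coded 1).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genome_io, repeats, seqstats, structure
from .genome_io import GenomeRecord
from .molevol import BranchTree
from .phylostats import phylo_anova, phylo_ttest, pgls

log = logging.getLogger(__name__)

VARIABLES = (
    "dispersed_repeat_n",
    "tandem_repeat_n",
    "rearrangement_distance",
    "indel_freq",
    "snv_freq",
    "gc",
    "gc_cds",
    "gc3",
    "dS",
)

GROUPS = ("IR_lacking", "IR_present", "CRCIR")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full comparison run; defaults are the survey's."""

    repeat_min_len: int = repeats.DEFAULT_MIN_REPEAT_LEN
    ssr_thresholds: Mapping[int, int] = field(
        default_factory=lambda: dict(repeats.DEFAULT_SSR_THRESHOLDS)
    )
    ssr_interruption: int = repeats.DEFAULT_SSR_INTERRUPTION
    association_window: int = repeats.DEFAULT_ASSOCIATION_WINDOW
    n_sim: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["ssr_thresholds"] = {str(k): v for k, v in self.ssr_thresholds.items()}
        return d


@dataclass
class ResultBundle:
    traits: pd.DataFrame  # taxon-indexed, VARIABLES + 'group'
    ttests: dict[str, "object"]
    pgls_results: dict[str, "object"]
    anova: dict[str, "object"]
    config: RunConfig
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(r):
            if r is None:
                return None
            out = {
                "method": r.method,
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                "estimates": dict(r.estimates),
            }
            if getattr(r, "posthoc", None) is not None:
                out["posthoc"] = json.loads(r.posthoc.to_json())
            return out

        return json.dumps(
            {
                "config": self.config.echo(),
                "metadata": self.metadata,
                "traits": json.loads(self.traits.to_json()),
                "ttests": {k: enc(v) for k, v in self.ttests.items()},
                "pgls": {k: enc(v) for k, v in self.pgls_results.items()},
                "anova": {k: enc(v) for k, v in self.anova.items()},
            },
            indent=2,
        )


def genome_traits(record: GenomeRecord, cfg: RunConfig = RunConfig()) -> dict[str, float]:
    """Sequence-derived variables for one plastome (IR collapsed first)."""
    rec = genome_io.collapse_ir(record)
    seq = rec.sequence
    reps = repeats.filter_redundant_repeats(
        repeats.find_dispersed_repeats(seq, min_len=cfg.repeat_min_len)
    )
    n_tandem = repeats.tandem_repeat_count(
        seq, thresholds=cfg.ssr_thresholds, interruption=cfg.ssr_interruption
    )
    cds = [
        rec.feature_sequence(f)
        for f in rec.features
        if f.kind == "CDS" and not f.pseudo and f.length % 3 == 0
    ]
    try:
        usage = seqstats.rscu(cds)
        gc_cds, gc3 = usage.gc, usage.gc3
    except ValueError:
        gc_cds = gc3 = float("nan")
    return {
        "dispersed_repeat_n": float(len(reps)),
        "tandem_repeat_n": float(n_tandem),
        "gc": seqstats.gc_content(seq),
        "gc_cds": gc_cds,
        "gc3": gc3,
    }


def rearrangement_distances(
    records: Sequence[GenomeRecord], reference_id: str
) -> dict[str, int]:
    """Reversal distance of each record to the reference over shared loci.

    IRs are collapsed, and for each comparison the distance is minimized
    over the two SSC isomers of the reference (the SSC orientation is
    arbitrary in IR-present plastomes).
    """
    collapsed = [genome_io.collapse_ir(r) for r in records]
    orders = genome_io.shared_locus_order(collapsed, reference_id)
    ref = next(r for r in collapsed if r.id == reference_id)
    ssc_loci: set[str] = set()
    if ref.partition is not None and ref.partition.ir_status != "none":
        s, e = ref.partition.ssc
        ssc_loci = {
            f.locus_name for f in ref.features if s <= f.start < e
        }
    out = {}
    for rec in collapsed:
        if rec.id == reference_id:
            out[rec.id] = 0
            continue
        d, _ = structure.distance_min_over_ssc(
            orders[rec.id], orders[reference_id], ssc_loci
        )
        out[rec.id] = d
    return out


def run_comparison(
    records: Sequence[GenomeRecord],
    tree: BranchTree,
    groups: Mapping[str, str],
    reference_id: str,
    alignments: Mapping[str, Mapping[str, str]] | None = None,
    ds_per_taxon: Mapping[str, float] | None = None,
    cfg: RunConfig = RunConfig(),
) -> ResultBundle:
    """The full comparative analysis on in-memory inputs.

    ``alignments`` optionally maps sequence class -> aligned FASTA dict
    (for indel/SNV frequencies vs the reference); ``ds_per_taxon``
    optionally supplies per-taxon synonymous rates (e.g. terminal-branch dS
    from a free-ratio codon-model fit).  Variables without inputs are
    reported as NaN and skipped by the tests.
    """
    ids = [r.id for r in records]
    tip_names = {tree.labels[v] for v in tree.tips}
    mismatch = set(ids) ^ tip_names
    if mismatch:
        raise ValueError(f"taxa inconsistent between genomes and tree: {sorted(mismatch)}")
    bad_groups = {t: g for t, g in groups.items() if g not in GROUPS}
    if bad_groups:
        raise ValueError(f"unknown group labels: {bad_groups}")

    rows = {}
    for rec in records:
        row = genome_traits(rec, cfg)
        rows[rec.id] = row
    dists = rearrangement_distances(records, reference_id)
    for t, d in dists.items():
        rows[t]["rearrangement_distance"] = float(d)
    for rec in records:
        t = rec.id
        if alignments is not None and t != reference_id:
            indel = seqstats.indel_frequency(alignments, t, reference_id, len(rec))
            snv = seqstats.snv_frequency(alignments, t, reference_id, len(rec))
            rows[t]["indel_freq"] = sum(indel.counts.values()) / indel.total_len
            rows[t]["snv_freq"] = sum(snv.counts.values()) / snv.total_len
        else:
            rows[t].setdefault("indel_freq", float("nan"))
            rows[t].setdefault("snv_freq", float("nan"))
        rows[t]["dS"] = float(ds_per_taxon.get(t, float("nan"))) if ds_per_taxon else float("nan")

    traits = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=VARIABLES)
    traits["group"] = [groups[t] for t in traits.index]

    # two-group phylogenetic t-test: IR_lacking (0) vs CRCIR (1)
    two = traits[traits["group"].isin(["IR_lacking", "CRCIR"])]
    ttests = {}
    sub_tree_pairs = _subtree(tree, list(two.index))
    for var in VARIABLES:
        vals = two[var]
        if vals.isna().any() or vals.nunique() <= 1:
            ttests[var] = None
            continue
        dummy = {t: (1 if g == "CRCIR" else 0) for t, g in two["group"].items()}
        ttests[var] = phylo_ttest(vals.to_dict(), dummy, sub_tree_pairs)

    # PGLS pairs on all taxa with data
    pgls_specs = {
        "dispersed_repeat_n~rearrangement_distance": ("rearrangement_distance", "dispersed_repeat_n"),
        "rearrangement_distance~dS": ("dS", "rearrangement_distance"),
    }
    pgls_results = {}
    for name, (xvar, yvar) in pgls_specs.items():
        sub = traits[[xvar, yvar]].dropna()
        if len(sub) < 3 or sub[xvar].nunique() <= 1:
            pgls_results[name] = None
            continue
        st = _subtree(tree, list(sub.index))
        pgls_results[name] = pgls(sub[yvar].to_dict(), sub[xvar].to_dict(), st)

    # three-group phylogenetic ANOVA with post-hoc tests
    anova = {}
    rng_seed = cfg.seed
    for var in VARIABLES:
        vals = traits[var]
        if vals.isna().any() or vals.nunique() <= 1 or traits["group"].nunique() < 2:
            anova[var] = None
            continue
        try:
            anova[var] = phylo_anova(
                vals.to_dict(), traits["group"].to_dict(), tree, n_sim=cfg.n_sim, seed=rng_seed
            )
        except ValueError as exc:  # degenerate variance structure
            log.warning("phylo_anova skipped for %s: %s", var, exc)
            anova[var] = None
    return ResultBundle(
        traits=traits,
        ttests=ttests,
        pgls_results=pgls_results,
        anova=anova,
        config=cfg,
        metadata={
            "reference": reference_id,
            "block_definition": "shared single-copy annotated loci (not Mauve LCBs)",
        },
    )


def _subtree(tree: BranchTree, keep: Sequence[str]) -> BranchTree:
    """Prune the tree to the named tips (via dendropy)."""
    import dendropy

    nwk = _to_newick(tree)
    t = dendropy.Tree.get(data=nwk, schema="newick")
    t.retain_taxa_with_labels(list(keep))
    return BranchTree.from_dendropy(t)


def _to_newick(tree: BranchTree) -> str:
    def rec(v: int) -> str:
        if not tree.children[v]:
            return f"{tree.labels[v]}:{tree.lengths[v]}"
        inner = ",".join(rec(c) for c in tree.children[v])
        blen = f":{tree.lengths[v]}" if tree.parent[v] >= 0 else ""
        return f"({inner}){blen}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Selection labeling and printed reference tables
# ---------------------------------------------------------------------------


def label_selection(omega0: float, omega1: float, p: float, alpha: float = 0.05):
    """Significance / selection-direction / selection-change labels.

    Selection direction follows the foreground omega (< 1 purifying =
    "Negative", > 1 "Positive").  The change label records whether the
    foreground omega moved toward 1 ("relaxation") or away from it
    ("intensification") relative to the single-ratio estimate; equal
    estimates yield no change label.
    """
    significance = "significant" if p < alpha else "not significant"
    if omega1 > 1:
        selection = "Positive"
    elif omega1 < 1:
        selection = "Negative"
    else:
        selection = "Neutral"
    d0, d1 = abs(1.0 - omega0), abs(1.0 - omega1)
    if d1 < d0:
        change = "relaxation"
    elif d1 > d0:
        change = "intensification"
    else:
        change = ""
    return significance, selection, change


def load_inversion_table() -> pd.DataFrame:
    """The published per-species inversion sites, lengths and boundary repeats."""
    with resources.files("plastevol.data").joinpath("inversion_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_selection_table() -> pd.DataFrame:
    """The published per-lineage branch-model omega estimates and labels."""
    with resources.files("plastevol.data").joinpath("selection_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def report(bundle: ResultBundle) -> str:
    """Human-readable summary of a comparison run."""
    lines = ["# Plastome comparison report", ""]
    lines.append("## Per-taxon variables")
    lines.append(bundle.traits.to_string(float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    lines.append("## Phylogenetic t-tests (IR_lacking vs CRCIR)")
    for var, r in bundle.ttests.items():
        if r is None:
            lines.append(f"{var}: (no data)")
        else:
            lines.append(
                f"{var}: diff={r.estimates['difference']:.4g} t={r.statistic:.3f} p={r.p:.4f}"
            )
    lines.append("")
    lines.append("## PGLS")
    for name, r in bundle.pgls_results.items():
        if r is None:
            lines.append(f"{name}: (no data)")
        else:
            lines.append(f"{name}: slope={r.estimates['slope']:.4g} p={r.p:.4f}")
    lines.append("")
    lines.append("## Phylogenetic ANOVA (three groups)")
    for var, r in bundle.anova.items():
        if r is None:
            lines.append(f"{var}: (no data)")
        else:
            lines.append(f"{var}: F={r.statistic:.3f} p={r.p:.4f}")
    return "\n".join(lines)


def selection_report(rows: Sequence[Mapping[str, float]], alpha: float = 0.05) -> pd.DataFrame:
    """Selection-table rendering: label each (omega0, omega1, p) row."""
    out = []
    for row in rows:
        sig, sel, change = label_selection(row["omega0"], row["omega1"], row["p_value"], alpha)
        out.append(
            dict(
                lineage=row.get("lineage", ""),
                omega0=row["omega0"],
                omega1=row["omega1"],
                p_value=row["p_value"],
                significance=sig,
                selection=sel,
                change=change,
            )
        )
    return pd.DataFrame(out)
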