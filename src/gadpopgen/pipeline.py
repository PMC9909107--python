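"""Analysis orchestration: per-gene x per-population report tables,
interspecies MK runs, and rank-based group comparisons.

Report conventions mirror the field's summary-table style: per-site
diversity values are emitted on the x1e-4 scale (header-noted), and
neutrality statistics carry significance marks #, *, **, *** at
0.10 / 0.05 / 0.01 / 0.001.  No multiple-testing correction is applied
to the marks; a Benjamini–Hochberg column is emitted alongside, clearly
labelled as an addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import mkdivergence, neutrality, popstats, seqio
from .popstats import AlignmentSummary
from .seqio import CodingAlignment


@dataclass
class GeneConfig:
    name: str
    alignment: Path
    populations: Path | None = None
    outgroup: Path | None = None          # FASTA with one comparator/outgroup
    outgroup_id: str | None = None        # or an id already in the alignment
    regions: Path | None = None


@dataclass
class AnalysisConfig:
    genes: list[GeneConfig]
    output_dir: Path = Path("gadpopgen_out")
    window: tuple[int, int] = (10, 1)
    significance_method: str = "coalescent_null"
    significance_reps: int = 2000
    seed: int = 0
    site_classes: tuple[str, ...] = ("all", "syn", "nonsyn", "silent")
    operon: dict | None = None            # {"name": ..., "genes": [...]}
    table_id: int = 11

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genes = [
            GeneConfig(
                name=g["name"],
                alignment=base / g["alignment"],
                populations=base / g["populations"] if g.get("populations") else None,
                outgroup=base / g["outgroup"] if g.get("outgroup") else None,
                outgroup_id=g.get("outgroup_id"),
                regions=base / g["regions"] if g.get("regions") else None,
            )
            for g in raw["genes"]
        ]
        sig = raw.get("significance", {})
        win = raw.get("window", {})
        return cls(
            genes=genes,
            output_dir=base / raw.get("output_dir", "gadpopgen_out"),
            window=(win.get("size", 10), win.get("step", 1)),
            significance_method=sig.get("method", "coalescent_null"),
            significance_reps=sig.get("reps", 2000),
            seed=sig.get("seed", 0),
            operon=raw.get("operon"),
            table_id=raw.get("codon_table", 11),
        )

    def validate(self):
        for g in self.genes:
            for p in (g.alignment, g.populations, g.outgroup, g.regions):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")
        w, s = self.window
        if w < 1 or s < 1:
            raise ValueError("window size and step must be >= 1")


def load_gene(g: GeneConfig, table_id: int = 11) -> CodingAlignment:
    records = seqio.read_fasta(g.alignment, "nt")
    outgroup_id = g.outgroup_id
    if g.outgroup is not None:
        og_records = seqio.read_fasta(g.outgroup, "nt")
        if len(og_records) != 1:
            raise ValueError(f"{g.outgroup}: expected exactly one outgroup record")
        records = records + og_records
        outgroup_id = og_records[0].id
    populations = (
        seqio.read_population_map(g.populations) if g.populations else None
    )
    if populations is None:
        populations = {
            r.id: "all" for r in records if r.id != outgroup_id
        }
    aln = seqio.make_alignment(
        records, populations=populations, outgroup_id=outgroup_id,
        table_id=table_id,
    )
    return seqio.complete_deletion(aln)


def concatenate_genes(alns: list[CodingAlignment], name: str = "operon"
                      ) -> CodingAlignment:
    """Operon aggregate: concatenation of the member genes' codon
    columns, restricted to the ids shared by every member."""
    common = set(alns[0].ids)
    for a in alns[1:]:
        common &= set(a.ids)
    if len(common) < 2:
        raise ValueError("fewer than 2 shared records across genes")
    order = [i for i in alns[0].ids if i in common]
    seqs = {i: [] for i in order}
    for a in alns:
        for rid in order:
            rec = next(r for r in a.records if r.id == rid)
            seqs[rid].append(rec.seq)
    records = tuple(
        seqio.SequenceRecord(rid, "".join(seqs[rid]), "nt") for rid in order
    )
    og = alns[0].outgroup_id if all(a.outgroup_id == alns[0].outgroup_id
                                    for a in alns) else None
    pops = {k: v for k, v in alns[0].populations.items() if k in common}
    return CodingAlignment(
        records=records, populations=pops,
        outgroup_id=og if og in common else None,
        table_id=alns[0].table_id,
    )


# ---------------------------------------------------------------------------
# within-species run
# ---------------------------------------------------------------------------

_SCALE = 1e4  # report scale for per-site diversity values


def _diversity_row(gene: str, pop: str, summary: AlignmentSummary) -> dict:
    sites = popstats.count_sites_neigojobori(summary.aln)
    table = summary.table
    syn_pol, rep_pol = table.fractional_counts()
    est_all = summary.diversity("all")
    return {
        "gene": gene,
        "population": pop,
        "N": summary.n,
        "total_bases": int(sites.L_total),
        "syn_sites": round(sites.L_syn, 2),
        "nonsyn_sites": round(sites.L_nonsyn, 2),
        "S": table.S,
        "eta": table.eta,
        "singletons": table.n_singletons,
        "parsimony_informative": table.n_parsimony_informative,
        "syn_polymorphisms": round(syn_pol, 2),
        "rep_polymorphisms": round(rep_pol, 2),
        "theta_w_x1e4": est_all.theta_w * _SCALE,
        "pi_x1e4": (est_all.pi_jc if est_all.pi_jc is not None else est_all.pi)
        * _SCALE,
        "pi_syn_x1e4": summary.pi_jc("syn") * _SCALE,
        "pi_nonsyn_x1e4": summary.pi_jc("nonsyn") * _SCALE,
    }


def _neutrality_row(
    gene: str,
    pop: str,
    summary: AlignmentSummary,
    sfs,
    method: str,
    reps: int,
    rng: np.random.Generator,
) -> dict:
    row: dict = {"gene": gene, "population": pop, "N": summary.n}
    pvals: dict[str, float] = {}
    for cls in ("all", "syn", "nonsyn", "silent"):
        suite = neutrality.neutrality_suite(summary, cls, sfs=sfs if cls == "all" else None)
        key = {"all": "td", "syn": "td_syn", "nonsyn": "td_nonsyn",
               "silent": "td_silent"}[cls]
        row[key] = suite.tajima_d
        if not math.isnan(suite.tajima_d) and summary.n >= 4:
            pvals[key] = neutrality.test_significance(
                "tajima_d", suite.tajima_d, summary.n, suite.S,
                method=method, reps=reps, seed=rng,
            )
        if cls == "all":
            row["td_coding"] = suite.tajima_d  # pure-CDS input: coding == all
            row["fu_li_d_star"] = suite.fu_li_d_star
            row["fu_li_f_star"] = suite.fu_li_f_star
            row["achaz_y"] = suite.achaz_y
            row["fay_wu_h_norm"] = suite.fay_wu_h_norm
            row["zeng_e"] = suite.zeng_e
            row["fu_li_d"] = suite.fu_li_d
            row["fu_li_f"] = suite.fu_li_f
            for stat in ("fu_li_d_star", "fu_li_f_star"):
                v = row[stat]
                if not math.isnan(v) and summary.n >= 4 and method == "coalescent_null":
                    pvals[stat] = neutrality.test_significance(
                        stat, v, summary.n, suite.S, method="coalescent_null",
                        reps=reps, seed=rng,
                    )
    for key, p in pvals.items():
        row[f"{key}_p"] = p
        row[f"{key}_sig"] = neutrality.significance_stars(p)
    return row


def run_within_species(cfg: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Per gene x (pooled + each population): diversity and neutrality
    tables; an operon aggregate row when configured."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    alignments: dict[str, CodingAlignment] = {
        g.name: load_gene(g, cfg.table_id) for g in cfg.genes
    }
    if cfg.operon:
        members = [alignments[name] for name in cfg.operon["genes"]]
        alignments[cfg.operon.get("name", "operon")] = concatenate_genes(members)

    div_rows, neu_rows, region_frames = [], [], []
    for gene, aln in alignments.items():
        pops = sorted(set(aln.populations.values()))
        units = [("all_samples", None)] + [(p, {p}) for p in pops if len(pops) > 1]
        for label, selector in units:
            sub = aln if selector is None else aln.select_populations(selector)
            if sub.n_ingroup < 2:
                continue
            summary = AlignmentSummary(sub)
            sfs = (
                popstats.polarize(sub)
                if sub.outgroup_id is not None
                else None
            )
            div_rows.append(_diversity_row(gene, label, summary))
            neu_rows.append(
                _neutrality_row(
                    gene, label, summary, sfs,
                    cfg.significance_method, cfg.significance_reps, rng,
                )
            )
        gene_cfg = next((g for g in cfg.genes if g.name == gene), None)
        if gene_cfg is not None and gene_cfg.regions is not None:
            regions = seqio.read_region_spec(gene_cfg.regions)
            frame = popstats.region_stats(aln, regions)
            frame.insert(0, "gene", gene)
            region_frames.append(frame)

    diversity = pd.DataFrame(div_rows)
    neutrality_df = pd.DataFrame(neu_rows)
    p_cols = [c for c in neutrality_df.columns if c.endswith("_p")]
    if p_cols:
        flat = neutrality_df[p_cols].to_numpy().ravel()
        ok = ~np.isnan(flat)
        if ok.any():
            adj = np.full(flat.shape, np.nan)
            adj[ok] = sps.false_discovery_control(flat[ok], method="bh")
            adj = adj.reshape(neutrality_df[p_cols].shape)
            for k, c in enumerate(p_cols):
                neutrality_df[f"{c}_bh_adjusted_extra"] = adj[:, k]
    out = {"diversity": diversity, "neutrality": neutrality_df}
    if region_frames:
        out["regions"] = pd.concat(region_frames, ignore_index=True)
    return out


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            if name == "diversity":
                fh.write("# theta and pi columns are on the x1e-4 scale; "
                         "pi columns are Jukes-Cantor corrected\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# interspecies run
# ---------------------------------------------------------------------------


def run_interspecies(
    cfg: AnalysisConfig,
    comparators: dict[str, Path],
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """MK tests of each configured gene against comparator sequences
    (FASTA aligned to the gene's coordinates; one row per record)."""
    cfg.validate()
    rows = []
    for g in cfg.genes:
        if g.name not in comparators:
            continue
        aln = load_gene(g, cfg.table_id)
        for comp in seqio.read_fasta(comparators[g.name], "nt"):
            if comp.id in aln.ids:
                raise ValueError(
                    f"comparator {comp.id!r} is already in the ingroup "
                    f"(self-comparison rejected)"
                )
            tbl = mkdivergence.mk_test(mkdivergence.mk_counts(aln, comp))
            rows.append(
                {
                    "gene": g.name,
                    "comparator": comp.id,
                    "Pn": tbl.Pn, "Ps": tbl.Ps, "Dn": tbl.Dn, "Ds": tbl.Ds,
                    "NI": tbl.NI, "alpha": tbl.alpha, "DoS": tbl.DoS,
                    "fisher_p": tbl.fisher_p,
                    "verdict": mkdivergence.interpret(tbl, alpha_level),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def compare_populations(
    values: dict[str, list[float]],
    method: str = "kruskal_wallis",
    pairwise: bool = False,
) -> dict:
    """Rank-based comparison of a per-population statistic.

    Two groups route to the Wilcoxon rank-sum test; more groups use the
    Kruskal–Wallis H test (tie-corrected), with optional pairwise
    rank-sum follow-ups.
    """
    groups = {k: [v for v in vals if not math.isnan(v)] for k, vals in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if not vals:
            raise ValueError(f"group {name!r} has no observations")
    names = sorted(groups)
    if len(groups) == 2 or method == "wilcoxon_pairwise":
        a, b = (groups[n] for n in names[:2])
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        result = {"method": "wilcoxon_rank_sum", "statistic": float(stat),
                  "p_value": float(p)}
    else:
        arrays = [groups[n] for n in names]
        if len({v for a in arrays for v in a}) == 1:
            # every observation identical: H = 0 by convention
            result = {"method": "kruskal_wallis", "statistic": 0.0, "p_value": 1.0}
        else:
            stat, p = sps.kruskal(*arrays)
            result = {"method": "kruskal_wallis", "statistic": float(stat),
                      "p_value": float(p)}
    if pairwise and len(groups) > 2:
        table = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                s, p = sps.mannwhitneyu(
                    groups[names[i]], groups[names[j]], alternative="two-sided"
                )
                table.append({"group_a": names[i], "group_b": names[j],
                              "statistic": float(s), "p_value": float(p)})
        result["pairwise"] = table
    return result
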