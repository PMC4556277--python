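"""End-to-end dominance analysis pipeline.

Stages: load (or accumulate from a log) per-variable sociomatrices ->
transpose submission variables -> per-variable relationship properties
(N, h', p, DCI, unknown/1-way/2-way/tied) -> variable selection ->
David's scores, I&SI order and steepness on the designated status
variable -> NormDS-profile correlations and clustering -> Spearman tests
of rank against covariates.  Every randomized stage is seeded and the
machine-readable summary embeds the config hash and seeds, so identical
configs reproduce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from . import covariation, linearity, ranking
from .sociomatrix import Sociomatrix, transpose_submission

__all__ = ["AnalysisConfig", "PipelineError", "run_pipeline", "format_report"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run.

    ``transpose`` lists the submission-related variables whose matrices
    are mirrored around the diagonal before analysis; it must be a subset
    of the analysed variables.  A seed is mandatory because linearity and
    steepness use randomization tests.
    """

    variables: tuple[str, ...]
    status_variable: str
    seed: int
    transpose: tuple[str, ...] = ()
    variant: str = "pij"
    alpha: float = 0.05
    max_unknown_fraction: float = 0.25
    n_rand_linearity: int = 10000
    n_rand_steepness: int = 20000
    rerandomize_all_dyads: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "transpose", tuple(self.transpose))
        if not set(self.transpose) <= set(self.variables):
            raise ValueError("transpose list must be a subset of variables")
        if self.status_variable not in self.variables:
            raise ValueError("status_variable must be among variables")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named re-raise
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("properties")
def _variable_properties(name: str, m: Sociomatrix, cfg: AnalysisConfig):
    rel = linearity.classify_relationships(m)
    lin = linearity.linearity_test(
        m, n_rand=cfg.n_rand_linearity, seed=cfg.seed,
        rerandomize_all_dyads=cfg.rerandomize_all_dyads,
    )
    d = linearity.dci(m)
    return rel, lin, d


def run_pipeline(
    matrices: Mapping[str, Sociomatrix],
    config: AnalysisConfig,
    covariates: Optional[pd.DataFrame] = None,
    outdir: Optional[str] = None,
) -> dict:
    """Run the full analysis and return the machine-readable summary.

    ``matrices`` maps variable name -> sociomatrix (counts as observed;
    submission variables are transposed here according to the config).
    ``covariates`` is an optional per-individual table (e.g. age, weight)
    indexed by the matrix labels.  When ``outdir`` is given, CSV/text
    reports and the JSON summary are written there; partial outputs are
    retained if a later stage fails.
    """
    missing = [v for v in config.variables if v not in matrices]
    if missing:
        raise PipelineError("load", f"missing matrices for variables {missing}")

    analysed: dict[str, Sociomatrix] = {}
    for name in config.variables:
        m = matrices[name]
        analysed[name] = transpose_submission(m) if name in config.transpose else m

    summary: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "variant": config.variant,
        "n_randomizations": {
            "linearity": config.n_rand_linearity,
            "steepness": config.n_rand_steepness,
        },
        "variables": {},
    }
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    rels: dict[str, linearity.RelationshipSummary] = {}
    lins: dict[str, linearity.LinearityResult] = {}
    prop_rows = []
    for name, m in analysed.items():
        rel, lin, d = _variable_properties(name, m, config)
        rels[name], lins[name] = rel, lin
        summary["variables"][name] = {
            "N": m.total,
            "h": round(lin.h, 4),
            "h_prime": round(lin.h_prime, 4),
            "p_linearity": lin.p_right,
            "dci": None if d.dci is None else round(d.dci, 4),
            "unknown": rel.unknown, "unknown_pct": rel.pct(rel.unknown),
            "one_way": rel.one_way, "one_way_pct": rel.pct(rel.one_way),
            "two_way": rel.two_way, "two_way_pct": rel.pct(rel.two_way),
            "tied": rel.tied, "tied_pct": rel.pct(rel.tied),
        }
        prop_rows.append({"variable": name, **summary["variables"][name]})

    # -- ranking and steepness on the designated status variable --------
    try:
        status = analysed[config.status_variable]
        dp = ranking.dyadic_proportions(status, config.variant)
        scores = ranking.david_scores(dp)
        order = ranking.isi_order(status, seed=config.seed)
        steep = ranking.steepness_test(
            status, config.variant, n_rand=config.n_rand_steepness,
            seed=config.seed,
        )
    except PipelineError:
        raise
    except Exception as exc:
        _dump(summary, prop_rows, outdir)
        raise PipelineError("ranking", str(exc)) from exc

    summary["status_variable"] = config.status_variable
    summary["scores"] = {
        lbl: {"NormDS": round(float(v), 4), "rank": int(r)}
        for lbl, v, r in zip(scores.labels, scores.normds, scores.ordinal_rank)
    }
    summary["isi_order"] = list(order.order)
    summary["isi_I"] = order.inconsistencies
    summary["isi_SI"] = order.strength
    summary["steepness"] = {
        "value": round(steep.steepness, 4),
        "intercept": round(steep.intercept, 4),
        "variant": steep.variant,
        "null_mean": round(steep.null_mean, 4),
        "p_right": steep.p_right,
    }

    # -- covariation ------------------------------------------------------
    try:
        selected = covariation.select_variables(
            lins, rels, alpha=config.alpha,
            max_unknown_fraction=config.max_unknown_fraction,
        )
        summary["selected_variables"] = selected
        if len(selected) >= 2:
            prof_scores = {
                name: ranking.david_scores(
                    ranking.dyadic_proportions(analysed[name], config.variant)
                )
                for name in selected
            }
            pm = covariation.profile_matrix(prof_scores)
            corr = covariation.profile_correlations(pm)
            dend = covariation.average_linkage_cluster(corr)
            summary["profile_correlations"] = {
                a: {b: round(float(corr.loc[a, b]), 4) for b in corr.columns}
                for a in corr.index
            }
            summary["dendrogram_newick"] = dend.to_newick()
            if outdir:
                corr.to_csv(os.path.join(outdir, "profile_correlations.csv"))
                dend.to_merge_table().to_csv(
                    os.path.join(outdir, "dendrogram_merges.csv"), index=False)
                with open(os.path.join(outdir, "dendrogram.nwk"), "w") as fh:
                    fh.write(dend.to_newick() + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        _dump(summary, prop_rows, outdir)
        raise PipelineError("covariation", str(exc)) from exc

    # -- covariate correlations ------------------------------------------
    if covariates is not None:
        cov_block = {}
        cov = covariates.loc[list(scores.labels)]
        for col in cov.columns:
            r_s, p = covariation.spearman_rank_correlation(scores, cov[col])
            cov_block[col] = {"r_s": round(float(r_s), 4), "p_one_tailed": round(float(p), 4)}
        summary["covariates"] = cov_block

    _dump(summary, prop_rows, outdir, scores=scores)
    return summary


def _dump(summary, prop_rows, outdir, scores=None) -> None:
    if not outdir:
        return
    pd.DataFrame(prop_rows).to_csv(
        os.path.join(outdir, "variable_properties.csv"), index=False)
    if scores is not None:
        scores.to_dataframe().to_csv(os.path.join(outdir, "scores.csv"))
    with open(os.path.join(outdir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "report.txt"), "w", encoding="utf-8") as fh:
        fh.write(format_report(summary))


def format_report(summary: dict) -> str:
    """Human-readable report mirroring the per-variable property table."""
    lines = [
        f"domhier analysis report  (config {summary['config_hash']}, "
        f"seed {summary['seed']})",
        "",
        f"{'variable':<18}{'N':>7}{'h_prime':>9}{'p':>10}{'DCI':>7}"
        f"{'Unknown':>12}{'1-Way':>12}{'2-Way':>12}{'Tied':>12}",
    ]
    for name, row in summary["variables"].items():
        d = "   --" if row["dci"] is None else f"{row['dci']:.2f}"
        lines.append(
            f"{name:<18}{row['N']:>7}{row['h_prime']:>9.2f}{row['p_linearity']:>10.4f}"
            f"{d:>7}"
            f"{row['unknown']:>5} ({row['unknown_pct']:>4.1f}%)"
            f"{row['one_way']:>5} ({row['one_way_pct']:>4.1f}%)"
            f"{row['two_way']:>5} ({row['two_way_pct']:>4.1f}%)"
            f"{row['tied']:>5} ({row['tied_pct']:>4.1f}%)"
        )
    if "steepness" in summary:
        s = summary["steepness"]
        lines += [
            "",
            f"status variable: {summary['status_variable']} "
            f"(variant {s['variant']})",
            f"I&SI order: {' > '.join(summary['isi_order'])} "
            f"(I={summary['isi_I']}, SI={summary['isi_SI']})",
            f"steepness = {s['value']:.2f} (null mean {s['null_mean']:.2f}, "
            f"right-tailed p = {s['p_right']:.4f})",
        ]
    if "covariates" in summary:
        for name, row in summary["covariates"].items():
            lines.append(
                f"Spearman rank ~ {name}: r_s = {row['r_s']:.2f}, "
                f"one-tailed p = {row['p_one_tailed']:.2f}"
            )
    return "\n".join(lines) + "\n"
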