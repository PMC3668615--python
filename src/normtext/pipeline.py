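"""End-to-end analysis pipeline.

Reads a responses table (and optionally participants), preprocesses the
text, runs take-one-out scoring per dataset, cross-dataset scoring in both
directions, pooled scoring, vocabulary comparisons with rarefaction at the
smaller dataset's size, the length contrast, the same/other x dataset
factorial analysis, the clip-homogeneity correlation, and (when demographics
are available) the crossed random-effects demographic models.  All result
tables are written as CSV together with a run manifest (config hash, seeds,
package versions).  Stages that need two datasets are skipped with a logged
notice when only one is present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import inference, io, scoring, vocabulary
from .textprep import (
    TokenizationRules,
    build_term_document_matrix,
    default_stopwords,
    load_stopwords,
    tokenized_response,
)

log = logging.getLogger("normtext")

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    responses_path: str
    out_dir: str
    participants_path: str | None = None
    stopwords_path: str | None = None  # None -> packaged default list
    rules: TokenizationRules = field(default_factory=TokenizationRules)
    combine_prompts: bool = True
    exclude_same_participant: bool = False
    rarefaction_replicates: int = 1000
    rarefaction_seed: int = 0
    top_k_distinctive: int = 15
    run_demographic_effects: bool = True
    effects_predictors: tuple[str, ...] = ("age", "gender", "education")
    estimation: str = "REML"  # or "ML"

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML or JSON key-value file."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "rules" in raw:
            raw["rules"] = TokenizationRules(**raw["rules"])
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = round(dt, 3)
            if exc_type is not None:
                log.error("stage %s: failed after %.2fs (%s)", name, dt, exc)
                return False
            log.info("stage %s: done in %.2fs", name, dt)
            return None

    return _Timer()


def run_pipeline(config: AnalysisConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the written reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seeds": {"rarefaction": config.rarefaction_seed},
        "versions": {
            "normtext": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "skipped": [],
    }
    paths: dict[str, Path] = {}

    with _stage("read", manifest):
        participants = (
            io.read_participants(config.participants_path)
            if config.participants_path
            else None
        )
        resp_df = io.read_responses(config.responses_path, participants)
        stoplist = (
            load_stopwords(config.stopwords_path)
            if config.stopwords_path
            else default_stopwords()
        )

    with _stage("textprep", manifest):
        labels = sorted(resp_df["dataset"].unique())
        raw_by_label = {
            lb: io.responses_from_frame(resp_df[resp_df["dataset"] == lb])
            for lb in labels
        }
        tok = {
            lb: [
                tokenized_response(r, stoplist, config.rules, config.combine_prompts)
                for r in raws
            ]
            for lb, raws in raw_by_label.items()
        }
        tdm = {
            lb: build_term_document_matrix(
                raws, stoplist, config.rules, config.combine_prompts
            )
            for lb, raws in raw_by_label.items()
        }

    with _stage("scoring", manifest):
        results = {
            lb: scoring.take_one_out(
                tok[lb], exclude_same_participant=config.exclude_same_participant
            )
            for lb in labels
        }
        for lb in labels:
            p = out / f"scores_{lb}.csv"
            scoring.results_to_frame(results[lb]).to_csv(p, index=False)
            paths[f"scores_{lb}"] = p
        if len(labels) >= 2:
            for qa in labels:
                for qb in labels:
                    if qa == qb:
                        continue
                    cross = scoring.cross_dataset_scores(tok[qa], tok[qb])
                    p = out / f"cross_{qa}_vs_{qb}.csv"
                    scoring.results_to_frame(cross).to_csv(p, index=False)
                    paths[f"cross_{qa}_vs_{qb}"] = p
            pooled = scoring.pooled_scores(
                [tok[lb] for lb in labels],
                exclude_same_participant=config.exclude_same_participant,
            )
            p = out / "pooled_scores.csv"
            scoring.results_to_frame(pooled).to_csv(p, index=False)
            paths["pooled_scores"] = p
        else:
            manifest["skipped"].append("cross_dataset_and_pooled")
            log.info("single dataset: cross-dataset and pooled scoring skipped")

    with _stage("vocabulary", manifest):
        vstats = [vocabulary.vocabulary_stats(tdm[lb], lb) for lb in labels]
        vdf = pd.DataFrame([dataclasses.asdict(v) for v in vstats])
        ratios = [scoring.same_other_ratio(results[lb]) for lb in labels]
        vdf["same_other_ratio"] = ratios
        p = out / "vocabulary.csv"
        vdf.to_csv(p, index=False)
        paths["vocabulary"] = p

        smallest = min(tdm[lb].n_docs for lb in labels)
        rare_rows = []
        for lb in labels:
            r = vocabulary.rarefy_vocabulary(
                tdm[lb],
                sample_size=smallest,
                replicates=config.rarefaction_replicates,
                seed=config.rarefaction_seed,
            )
            rare_rows.append({"dataset": lb, **dataclasses.asdict(r)})
        p = out / "rarefaction.csv"
        pd.DataFrame(rare_rows).to_csv(p, index=False)
        paths["rarefaction"] = p

        if len(labels) >= 2:
            a, b = labels[0], labels[1]
            shared, only_a, only_b = vocabulary.vocab_overlap(tdm[a], tdm[b])
            p = out / "overlap.csv"
            pd.DataFrame(
                [{"dataset_a": a, "dataset_b": b, "shared": shared,
                  "only_a": only_a, "only_b": only_b}]
            ).to_csv(p, index=False)
            paths["overlap"] = p
            da = vocabulary.distinctive_words(tdm[a], tdm[b], config.top_k_distinctive)
            da.insert(0, "present_in", a)
            db = vocabulary.distinctive_words(tdm[b], tdm[a], config.top_k_distinctive)
            db.insert(0, "present_in", b)
            p = out / "distinctive_words.csv"
            pd.concat([da, db], ignore_index=True).to_csv(p, index=False)
            paths["distinctive_words"] = p

        lsum = []
        for lb in labels:
            _, s = vocabulary.length_summary(tdm[lb], lb)
            lsum.append(s)
        ldf = pd.concat(lsum, ignore_index=True)
        if len(labels) >= 2:
            t, df_, pv = inference.welch_t(
                tdm[labels[0]].row_lengths(), tdm[labels[1]].row_lengths()
            )
            ldf["welch_t_vs_first"] = [math.nan] + [t] * (len(labels) - 1)
            ldf["welch_p_vs_first"] = [math.nan] + [pv] * (len(labels) - 1)
        p = out / "length_summary.csv"
        ldf.to_csv(p, index=False)
        paths["length_summary"] = p

    with _stage("inference", manifest):
        if len(labels) >= 2:
            fact = inference.same_other_factorial(
                [r for lb in labels for r in results[lb]]
            )
            p = out / "factorial.csv"
            pd.DataFrame(
                [{
                    "f_comparison": fact.f_comparison,
                    "p_comparison": fact.p_comparison,
                    "f_dataset": fact.f_dataset,
                    "p_dataset": fact.p_dataset,
                    "f_interaction": fact.f_interaction,
                    "p_interaction": fact.p_interaction,
                    "df_den": fact.df_den,
                }]
            ).to_csv(p, index=False)
            paths["factorial"] = p

            homog = {
                lb: {h.clip_id: h.mean_shared
                     for h in scoring.clip_homogeneity(results=results[lb])}
                for lb in labels
            }
            common = sorted(set(homog[labels[0]]) & set(homog[labels[1]]))
            hdf = pd.DataFrame(
                {
                    "clip_id": common,
                    labels[0]: [homog[labels[0]][c] for c in common],
                    labels[1]: [homog[labels[1]][c] for c in common],
                }
            )
            if len(common) >= 3:
                r, pv = inference.pearson_r(hdf[labels[0]], hdf[labels[1]])
                hdf.attrs["pearson_r"] = r
                manifest["homogeneity_r"] = r
                manifest["homogeneity_p"] = pv
            p = out / "homogeneity.csv"
            hdf.to_csv(p, index=False)
            paths["homogeneity"] = p
        else:
            manifest["skipped"].append("factorial_and_homogeneity")
            log.info("single dataset: factorial and homogeneity stages skipped")

        if config.run_demographic_effects and participants is not None:
            eff_rows = []
            for lb in labels:
                sdf = scoring.results_to_frame(results[lb]).rename(
                    columns={"dataset": "dataset_label"}
                )
                merged = sdf.merge(
                    resp_df[["response_id", "participant_id"]], on="response_id"
                ).merge(participants, on="participant_id")
                for outcome in ("mean_same", "word_count"):
                    ests = inference.demographic_effects(
                        merged,
                        outcome=outcome,
                        predictors=config.effects_predictors,
                        reml=config.estimation.upper() == "REML",
                    )
                    for e in ests:
                        eff_rows.append(
                            {
                                "dataset": lb,
                                "outcome": outcome,
                                "term": e.term,
                                "coefficient": e.coefficient,
                                "se": e.standard_error,
                                "p": e.p_value,
                                "method": e.metadata.get("method"),
                            }
                        )
            p = out / "effects.csv"
            pd.DataFrame(eff_rows).to_csv(p, index=False)
            paths["effects"] = p
        elif config.run_demographic_effects:
            manifest["skipped"].append("demographic_effects")
            log.info("no participants table: demographic effects skipped")

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1, default=str))
    paths["manifest"] = mp
    return paths
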