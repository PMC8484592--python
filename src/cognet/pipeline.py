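"""End-to-end orchestration of the three analysis studies.

A :class:`RunConfig` (usually loaded from YAML) names the inputs —
either file paths or a synthetic specification — picks the stages to
run, and fixes every seed. ``run_pipeline`` executes
corpus -> networks -> emotional balance -> SVO structure -> semantic
frames in order, writes each stage's tables under the output
directory, and records everything in a manifest. With identical
config and seeds the outputs are byte-identical across runs (no
timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import corpus_io, net_build, semantic_frames, signed_balance, svo_structure
from .corpus_io import write_network_csv
from .synthetic import (
    SyntheticSpec,
    generate_corpus,
    generate_fa_baseline,
    generate_lexicons,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build", "balance", "svo", "frames")


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "cognet_out"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    n_realizations: int = 1000
    alpha: float = 0.05
    k_clusters: int = 4
    n_profile_words: int = 3
    # file inputs (all optional when the simulate stage is enabled)
    corpus: str | None = None
    valence_lexicon: str | None = None
    emotion_lexicon: str | None = None
    fa_network: str | None = None
    min_sentences: int = 2
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def validate(self) -> None:
        """Fail fast: every enabled stage's inputs must be resolvable."""
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        simulated = "simulate" in self.stages
        needs_corpus = {"build", "balance", "svo", "frames"} & set(self.stages)
        if needs_corpus and not simulated:
            for name in ("corpus", "valence_lexicon"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"stage needs {name!r} but it is missing: {p}")
        if "frames" in self.stages and not simulated:
            p = self.emotion_lexicon
            if p is None or not Path(p).exists():
                raise ConfigError(f"frames stage needs an emotion lexicon: {p}")
        if self.n_realizations < 1 or not 0 < self.alpha < 1:
            raise ConfigError("invalid n_realizations or alpha")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("stages", "out_dir")  # location is not a parameter
        },
        "stages": list(config.stages),
        "outputs": {},
    }
    state: dict = {}

    def emit(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, []).append(str(path.relative_to(out)))

    def finish(error: Exception | None = None, stage: str | None = None):
        if error is not None:
            manifest["failed_stage"] = stage
        _write_json(manifest, out / "manifest.json")

    stage: str | None = None
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            _STAGE_FNS[stage](config, state, out, emit)
    except Exception as exc:  # preserve the partial manifest, then abort
        stage = getattr(exc, "stage", stage)
        finish(exc, stage)
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc
    finish()
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: RunConfig, state: dict, out: Path, emit) -> None:
    spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
    valence, emotions = generate_lexicons(spec)
    corpus, triples = generate_corpus(spec, valence)
    corpus = corpus_io.annotate_valence(corpus, valence)
    fa = generate_fa_baseline(spec)
    state.update(
        spec=spec, valence=valence, emotions=emotions, corpus=corpus,
        triples=triples, fa=fa,
    )
    corpus_io.write_corpus(corpus, out / "corpus.jsonl")
    corpus_io.write_valence_lexicon(valence, out / "valence_lexicon.tsv")
    corpus_io.write_emotion_lexicon(emotions, out / "emotion_lexicon.tsv")
    write_network_csv(fa, out / "fa_network.csv")
    with (out / "ground_truth_triples.csv").open("w", encoding="utf-8") as fh:
        fh.write("subject,verb,object,doc_id\n")
        for t in sorted(triples, key=lambda t: (t.doc_id, t.subject, t.verb, t.object)):
            fh.write(f"{t.subject},{t.verb},{t.object},{t.doc_id}\n")
    for name in ("corpus.jsonl", "valence_lexicon.tsv", "emotion_lexicon.tsv",
                 "fa_network.csv", "ground_truth_triples.csv"):
        emit("simulate", name, out / name)


def _stage_build(config: RunConfig, state: dict, out: Path, emit) -> None:
    if "corpus" not in state:
        valence = corpus_io.read_valence_lexicon(config.valence_lexicon)
        corpus = corpus_io.read_corpus(config.corpus, config.min_sentences)
        corpus = corpus_io.annotate_valence(corpus, valence)
        state.update(corpus=corpus, valence=valence)
        if config.emotion_lexicon:
            state["emotions"] = corpus_io.read_emotion_lexicon(config.emotion_lexicon)
    corpus = state["corpus"]
    co = net_build.build_cooccurrence(corpus)
    triples = state.get("triples")
    if not triples:
        triples = net_build.extract_svo_triples(corpus.sentences())
    valences = {
        corpus.concept(t): t.valence
        for s in corpus.sentences() for t in s.tokens
    }
    svo = net_build.build_svo_network(triples, valence=valences) if triples else None
    state.update(co=co, svo=svo)
    write_network_csv(co, out / "co_network.csv")
    emit("build", "co_network.csv", out / "co_network.csv")
    if svo is not None:
        write_network_csv(svo, out / "svo_network.csv")
        emit("build", "svo_network.csv", out / "svo_network.csv")
    if "fa" not in state and config.fa_network:
        state["fa"] = corpus_io.read_association_network(
            config.fa_network, vocab_filter=set(co.nodes)
        )


def _stage_balance(config: RunConfig, state: dict, out: Path, emit) -> None:
    rng = np.random.default_rng(config.seed + 10)
    reports = {}
    for label in ("co", "fa"):
        G = state.get(label)
        if G is None:
            continue
        if label == "fa":  # FA nodes carry no corpus valence; annotate from lexicon
            G = G.copy()
            val = state["valence"]
            for n in G.nodes:
                G.nodes[n]["valence"] = val.get(n, "neutral")
        signed = signed_balance.sign_edges(G)
        census = signed_balance.triad_census(signed)
        nulls = {
            "configuration": signed_balance.configuration_null(
                signed, config.n_realizations, seed=int(rng.integers(2**31))
            ),
            "label_shuffle": signed_balance.label_shuffle_null(
                signed, config.n_realizations, seed=int(rng.integers(2**31))
            ),
        }
        report = signed_balance.balance_report(census, nulls)
        path = out / f"balance_{label}.csv"
        report.to_csv(path, index=False, float_format="%.6f")
        emit("balance", path.name, path)
        write_network_csv(signed, out / f"signed_{label}.csv", signed=True)
        emit("balance", f"signed_{label}.csv", out / f"signed_{label}.csv")
        reports[label] = {
            "census": dataclasses.asdict(census),
            "dob": census.dob,
        }
        if label == "co":
            state["co_census"] = census
            state["co_nulls"] = nulls
    _write_json(reports, out / "balance_summary.json")
    emit("balance", "balance_summary.json", out / "balance_summary.json")


def _stage_svo(config: RunConfig, state: dict, out: Path, emit) -> None:
    svo = state.get("svo")
    if svo is None:
        logger.warning("no SVO network; skipping SVO structure stage")
        return
    strengths = net_build.node_strengths(svo)
    gc = max(nx.connected_components(svo), key=len)
    sub = svo.subgraph(gc)
    report: dict = {
        "n_nodes": svo.number_of_nodes(),
        "giant_fraction_nodes": len(gc) / svo.number_of_nodes(),
        "giant_fraction_strength": sum(strengths[v] for v in gc) / sum(strengths.values()),
        "degeneracy_gc": svo_structure.degeneracy(sub),
    }
    try:
        fit = svo_structure.tail_exponent(list(strengths.values()))
        report["tail_fit"] = dataclasses.asdict(fit)
    except (svo_structure.InsufficientDataError, svo_structure.NoFitError) as exc:
        report["tail_fit"] = {"error": str(exc)}

    hubs = sorted(gc, key=lambda v: (-strengths[v], str(v)))[:5]
    nulls = svo_structure.soft_cm_shrinkage_null(
        svo, hubs, max(100, config.n_realizations), seed=config.seed + 20
    )
    report["hubs"] = []
    for v in hubs:
        nd = nulls[v]
        n_dep, frac, frac_neg = svo_structure.articulation_share(svo, v)
        entry = {
            "node": v,
            "strength": strengths[v],
            "shrinkage": nd.observed,
            "shrinkage_null": {
                "mean": nd.null.mean, "centile_1": nd.centile_1,
                "centile_99": nd.centile_99, "p_value": nd.p_value,
                "outlier": nd.outlier,
            },
            "articulation": {
                "n_dependent": n_dep, "fraction_of_gc": frac,
                "fraction_negative_dependent": frac_neg,
            },
        }
        try:
            nv = svo_structure.neighborhood_valence_test(svo, v)
            entry["neighborhood_valence"] = dataclasses.asdict(nv)
        except svo_structure.InsufficientDataError:
            pass
        report["hubs"].append(entry)

    k = min(config.k_clusters, len(gc))
    partition = svo_structure.gn_clusters(svo, k)
    report["clusters"] = svo_structure.cluster_report(svo, partition)
    state["svo_report"] = report
    _write_json(report, out / "svo_structure.json")
    emit("svo", "svo_structure.json", out / "svo_structure.json")


def _stage_frames(config: RunConfig, state: dict, out: Path, emit) -> None:
    co = state.get("co")
    if co is None:
        co = net_build.build_cooccurrence(state["corpus"])
    emotions = state["emotions"]
    stop = {n for n, d in co.nodes(data=True) if d.get("is_stopword")}
    ranking = semantic_frames.closeness_ranking(co, exclude=stop)
    path = out / "closeness_ranking.csv"
    with path.open("w", encoding="utf-8") as fh:
        fh.write("word,closeness,rank\n")
        for w, c, r in ranking.entries:
            fh.write(f"{w},{c:.6f},{r}\n")
    emit("frames", path.name, path)

    rng = np.random.default_rng(config.seed + 30)
    fa = state.get("fa")
    targets = [w for w, _, _ in ranking.entries[: config.n_profile_words]]
    profiles = {}
    for w in targets:
        frame = semantic_frames.semantic_frame(co, w)
        prof = semantic_frames.emotion_profile(
            frame, emotions, n_samples=max(100, config.n_realizations),
            alpha=config.alpha, seed=int(rng.integers(2**31)), target=w,
        )
        profiles[w] = {"co": prof}
        if fa is not None and w in fa:
            fa_frame = semantic_frames.semantic_frame(fa, w)
            try:
                fa_prof = semantic_frames.emotion_profile(
                    fa_frame, emotions, n_samples=max(100, config.n_realizations),
                    alpha=config.alpha, seed=int(rng.integers(2**31)), target=w,
                )
                profiles[w]["fa"] = fa_prof
            except semantic_frames.InsufficientOverlapError:
                pass

    summary = {}
    for w, p in profiles.items():
        summary[w] = {
            "co": {e: dataclasses.asdict(r) for e, r in p["co"].records.items()}
        }
        if "fa" in p:
            summary[w]["fa"] = {
                e: dataclasses.asdict(r) for e, r in p["fa"].records.items()
            }
            contrast = semantic_frames.compare_profiles(p["co"], p["fa"])
            cpath = out / f"profile_contrast_{w.replace('/', '_')}.csv"
            contrast.to_csv(cpath, index=False, float_format="%.6f")
            emit("frames", cpath.name, cpath)
    _write_json(summary, out / "emotion_profiles.json")
    emit("frames", "emotion_profiles.json", out / "emotion_profiles.json")

    if targets:
        obs, null_mean, shift = semantic_frames.rank_shift_under_null(
            co, targets[0], n_realizations=min(100, config.n_realizations),
            seed=config.seed + 31, exclude=stop,
        )
        rank_info = {
            "word": targets[0], "observed_rank": obs,
            "null_mean_rank": null_mean, "shift": shift,
        }
        _write_json(rank_info, out / "rank_shift.json")
        emit("frames", "rank_shift.json", out / "rank_shift.json")
        state["rank_shift"] = rank_info


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "build": _stage_build,
    "balance": _stage_balance,
    "svo": _stage_svo,
    "frames": _stage_frames,
}
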