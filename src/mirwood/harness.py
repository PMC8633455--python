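"""Simulate -> run -> evaluate studies over seeds.

Each function here runs real pipeline stages on freshly simulated data (or on
freshly drawn random instances) and scores the outcome against planted truth
or an independent reference routine.  They are the package's own evaluation
harness: property-level checks a maintainer can run to convince themselves
the pipeline behaves as documented.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, discovery, expression, qc, structure, targets, validation
from ._seq import revcomp_rna, transcribe
from .pipeline import PipelineConfig, read_fastq_counted, run_pipeline
from .simulate import SimulationConfig, simulate_dataset


def fold_oracle_study(seed: int, n_sequences: int = 1000,
                      max_len: int = 20) -> dict:
    """Compare fold() energies against exhaustive enumeration on short RNAs."""
    rng = np.random.default_rng(seed)
    disagreements = 0
    for _ in range(n_sequences):
        n = int(rng.integers(10, max_len + 1))
        seq = "".join(rng.choice(list("ACGU"), n))
        mfe = structure.fold(seq).mfe
        ref, _ = structure.min_energy_exhaustive(seq)
        if abs(mfe - ref) > 1e-6:
            disagreements += 1
    return {"n": n_sequences, "disagreements": disagreements}


def duplex_rule_study(seed: int, n_duplexes: int = 10_000) -> dict:
    """Compare the duplex rule scorer against the independent checker."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    disagreements = 0
    for _ in range(n_duplexes):
        L = int(rng.integers(18, 26))
        mirna = "".join(rng.choice(bases, L))
        if rng.random() < 0.5:
            site = "".join(rng.choice(bases, L))
        else:
            site = list(revcomp_rna(mirna))
            for _k in range(int(rng.integers(0, 7))):
                site[int(rng.integers(0, L))] = str(rng.choice(bases))
            site = "".join(site)
        hit = targets.score_duplex(mirna, site)
        ref = validation.check_target_rules(mirna, site)
        same = all(hit.rule_pass[r] == ref[r] for r in hit.rule_pass)
        same &= abs(hit.total_weighted
                    - sum(validation.position_weights(mirna, site))) < 1e-9
        if not same:
            disagreements += 1
    return {"n": n_duplexes, "disagreements": disagreements}


def _discover_on_bundle(bundle: Path, cfg: PipelineConfig):
    """QC -> collapse -> annotate -> novel prediction on one bundle."""
    clean = {}
    for p in sorted(bundle.glob("srna_*.fastq.gz")):
        c, rep = qc.clean_srna_counted(read_fastq_counted(p), cfg.adapter_3p,
                                       cfg.adapter_5p)
        assert rep.conserved()
        clean[p.name[5:-9]] = c
    tags = annotate.collapse_tags(clean)
    refs = annotate.load_reference_bundle(bundle)
    annotations = annotate.annotate_tags(tags, refs)
    unannotated = [a.tag for a in annotations if a.category == "unannotated"]
    cands = discovery.predict_novel(unannotated, refs.genome, cfg.discovery,
                                    index=refs.index)
    return cands, discovery.dedupe_candidates(cands)


def hairpin_recovery_study(base_seed: int, n_seeds: int = 20,
                           config_overrides: dict | None = None) -> dict:
    """Recall of planted hairpins at generator defaults, plus independent
    re-validation of every reported candidate."""
    cfg = PipelineConfig()
    planted = recovered = 0
    n_candidates = invalid = 0
    for k in range(n_seeds):
        sim = SimulationConfig(seed=int(base_seed) + k,
                               **(config_overrides or {}))
        with tempfile.TemporaryDirectory() as tmp:
            _, truth = simulate_dataset(sim, tmp)
            cands, records = _discover_on_bundle(Path(tmp), cfg)
        found = {r.mature_seq for r in records}
        for hp in truth.planted_hairpins:
            planted += 1
            recovered += transcribe(hp["mature"]) in found
        for c in cands:
            n_candidates += 1
            res = validation.revalidate_hairpin(
                c.precursor_seq, c.mature_tag.seq, c.fold.structure,
                c.copies_on_reference)
            invalid += not res["all"]
    return {"n_seeds": n_seeds, "planted": planted, "recovered": recovered,
            "recall": recovered / planted if planted else float("nan"),
            "n_candidates": n_candidates, "invalid_candidates": invalid}


def _nb_draw(rng, mu, size, dispersion):
    if dispersion < 1e-12:
        return rng.poisson(mu, size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu), size=size)


def de_calibration_study(seed: int, n_null: int = 10_000,
                         dispersion: float = 0.05, replicates: int = 3) -> dict:
    """Type-I error of the exact test at p <= 0.05 on null NB features."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_null):
        mu = float(rng.lognormal(4.5, 0.5))
        a = _nb_draw(rng, mu, replicates, dispersion)
        b = _nb_draw(rng, mu, replicates, dispersion)
        if expression.nb_exact_test(a, b, dispersion) <= 0.05:
            hits += 1
    return {"n": n_null, "type1_rate": hits / n_null}


def de_power_study(seed: int, n_effect: int = 2000, n_null: int = 8000,
                   effect_log2fc: float = 3.0, dispersion: float = 0.05) -> dict:
    """Sensitivity and FDP of the miRNA DE caller on planted NB effects."""
    rng = np.random.default_rng(seed)
    libs = ["PS1", "PS2", "PS3", "TS1", "TS2", "TS3"]
    rows, is_effect = [], []
    for i in range(n_effect):
        mu = float(rng.lognormal(4.5, 0.5))
        f = 2.0 ** (effect_log2fc if i % 2 == 0 else -effect_log2fc)
        rows.append(np.concatenate([_nb_draw(rng, mu, 3, dispersion),
                                    _nb_draw(rng, mu * f, 3, dispersion)]))
        is_effect.append(True)
    for _ in range(n_null):
        mu = float(rng.lognormal(4.5, 0.5))
        rows.append(np.concatenate([_nb_draw(rng, mu, 3, dispersion),
                                    _nb_draw(rng, mu, 3, dispersion)]))
        is_effect.append(False)
    df = pd.DataFrame(rows, columns=libs,
                      index=[f"f{i}" for i in range(len(rows))])
    m = expression.ExpressionMatrix(df, library_totals=pd.Series(1_000_000,
                                                                 index=libs))
    de = expression.call_de_mirnas(m, ("PS", "TS"), {l: l[:-1] for l in libs})
    truth = np.array(is_effect)
    called = de["called"].to_numpy()
    return {
        "n_effect": n_effect, "n_null": n_null,
        "sensitivity": float(called[truth].mean()),
        "fdp": float((called & ~truth).sum() / max(int(called.sum()), 1)),
    }


def tpm_conservation_study(seed: int, n_features: int = 200,
                           n_libraries: int = 9) -> dict:
    """Column-sum conservation at 1e6 and the exact worked example."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.integers(0, 2000, size=(n_features, n_libraries)),
                      columns=[f"L{i}" for i in range(n_libraries)])
    tpm = expression.tpm_normalize(expression.ExpressionMatrix(df))
    max_dev = float(np.abs(tpm.sum(axis=0) - 1e6).max())
    worked = expression.tpm_normalize(expression.ExpressionMatrix(
        pd.DataFrame({"L": [1]}),
        library_totals=pd.Series({"L": 1_000_000}))).iloc[0, 0]
    return {"n": n_features * n_libraries, "max_column_deviation": max_dev,
            "worked_example": float(worked)}


def negative_pair_study(base_seed: int, n_seeds: int = 3,
                        config_overrides: dict | None = None) -> dict:
    """Sensitivity of negative-pair classification across small full runs."""
    overrides = dict(genome_length=250_000, n_genes=100, n_novel_hairpins=5,
                     n_known_mirnas=16, library_depth=8_000, n_de_mirnas=6,
                     mrna_library_depth=400_000)
    overrides.update(config_overrides or {})
    planted = recovered = n_pairs = n_positive = 0
    for k in range(n_seeds):
        sim = SimulationConfig(seed=int(base_seed) + 1000 + k, **overrides)
        with tempfile.TemporaryDirectory() as tmp:
            _, truth = simulate_dataset(sim, Path(tmp) / "bundle")
            result = run_pipeline(Path(tmp) / "bundle", Path(tmp) / "out")
        seq_of = {r.name: r.mature_seq
                  for r in result.known_records + result.novel_records}
        neg_found = set()
        for recs in result.pair_records.values():
            for _, row in recs.iterrows():
                n_pairs += 1
                n_positive += row["cls"] == "positive"
                if row["cls"] == "negative":
                    neg_found.add((seq_of.get(row["mirna"], ""), row["ctg"]))
        for pair in truth.planted_negative_pairs:
            planted += 1
            recovered += tuple(pair) in neg_found
    return {"n_seeds": n_seeds, "planted": planted, "recovered": recovered,
            "sensitivity": recovered / planted if planted else float("nan"),
            "n_pairs": n_pairs, "n_positive": n_positive,
            "positive_rate": n_positive / n_pairs if n_pairs else 0.0}


def enrichment_null_study(seed: int, n_draws: int = 50) -> dict:
    """Hypergeometric null behaviour on random study sets."""
    from .enrich import enrich

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(120)]
    rows = []
    for t in range(30):
        for g in genes:
            if rng.random() < 0.1:
                rows.append({"gene_id": g, "term_id": f"T{t:02d}",
                             "term_name": f"term{t}", "namespace": "BP"})
    ann = pd.DataFrame(rows)
    n_raw = n_sig = n_terms = 0
    for _ in range(n_draws):
        study = set(rng.choice(genes, 15, replace=False))
        if not (set(ann["gene_id"]) & study):
            continue
        res = enrich(study, set(genes), ann)
        n_raw += int((res["p"] <= 0.05).sum())
        n_sig += int(res["significant"].sum())
        n_terms += len(res)
    return {"n_terms_tested": n_terms,
            "raw_p05_rate": n_raw / max(n_terms, 1),
            "fdr05_rate": n_sig / max(n_terms, 1)}


def pipeline_accounting_study(seed: int) -> dict:
    """Full-run accounting identities plus rerun determinism."""
    overrides = dict(genome_length=250_000, n_genes=100, n_novel_hairpins=5,
                     n_known_mirnas=16, library_depth=8_000, n_de_mirnas=6,
                     mrna_library_depth=400_000)
    sim = SimulationConfig(seed=int(seed), **overrides)
    with tempfile.TemporaryDirectory() as tmp:
        simulate_dataset(sim, Path(tmp) / "bundle")
        r1 = run_pipeline(Path(tmp) / "bundle", Path(tmp) / "out1")
        r2 = run_pipeline(Path(tmp) / "bundle", Path(tmp) / "out2")
    conserved = all(rep.conserved() for rep in r1.qc_reports.values())
    clean_total = sum(rep.clean for rep in r1.qc_reports.values())
    cat_total = sum(r1.manifest.counts["category_totals"].values())
    partition = all(
        s["n_pairs"] == s["n_negative"] + s["n_positive"] + s["n_none"]
        for s in r1.pair_summaries.values())
    cards = all(
        r1.networks[c]["n_unique_mirnas"]
        == len(set(r1.pair_records[c].query("cls == 'negative'")["mirna"]))
        and r1.networks[c]["n_unique_ctgs"]
        == len(set(r1.pair_records[c].query("cls == 'negative'")["ctg"]))
        for c in r1.pair_records)
    return {
        "qc_conserved": conserved,
        "category_totals_match_clean": cat_total == clean_total,
        "pair_classes_partition": partition,
        "network_cardinalities_match": cards,
        "rerun_identical": r1.manifest.signature() == r2.manifest.signature(),
    }
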