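import pytest

from exact import (
    GeneratorConfig,
    default_rules,
    default_schema,
    generate_corpus,
    preprocess_document,
    run_pipeline,
    train_models,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_corpus():
    """Six preprocessed articles with gold, for cheap unit tests."""
    docs, golds = generate_corpus(GeneratorConfig(n_articles=6, seed=42))
    ann = [preprocess_document(d) for d in docs]
    return docs, ann, golds


@pytest.fixture(scope="session")
def synth_loop(schema):
    """The closed training/evaluation loop: 60 training articles, 20 held out.

    Session-scoped because training is the expensive step; every consumer
    treats the contents as read-only.
    """
    specs, hierarchy = schema
    cfg = GeneratorConfig(n_articles=80, seed=1)
    docs, golds = generate_corpus(cfg)
    ann = [preprocess_document(d) for d in docs]
    model = train_models(ann[:60], golds[:60], specs, hierarchy, seed=1)
    rules = default_rules()
    results = {a.doc_id: run_pipeline(model, rules, a, specs) for a in ann[60:]}
    gold_map = {g.doc_id: g for g in golds[60:]}
    ann_map = {a.doc_id: a for a in ann[60:]}
    return {
        "config": cfg,
        "docs": docs,
        "annotated": ann,
        "golds": golds,
        "model": model,
        "rules": rules,
        "results": results,
        "gold_map": gold_map,
        "ann_map": ann_map,
    }
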