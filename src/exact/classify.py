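"""Sentence classification: per-node linear models with hierarchical scoring.

Each sentence is represented as a bag of terms: lowercased word unigrams,
bigrams and trigrams, entity pseudo-tokens (``TAG_integer``, ``TAG_date``,
...) and section-path tokens (``SEC_methods``).  A linear max-margin
classifier is trained for every non-root node of the element hierarchy:
leaf positives are the gold-relevant sentences for that element, internal
node positives are the union of the descendants' positives, so evidence
from semantically related elements is pooled.  Raw margins are mapped to
probabilities by a monotone sigmoid (Platt) calibration fitted on the
training margins.

A sentence's confidence for a leaf element is the product of the calibrated
probabilities along the root-to-leaf path (root excluded); untrainable nodes
contribute a neutral factor of 1.  The product makes leaf confidence
monotonically non-increasing with depth.  A flat mode (leaf probability
only) is kept for ablation.
"""

from __future__ import annotations

import hashlib
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .io import GoldAnnotation
from .preprocess import AnnotatedDocument, Sentence
from .schema import (
    CITATION_ELEMENTS,
    ElementHierarchy,
    ElementSpec,
    ROOT,
    SchemaError,
)

__all__ = [
    "FeatureVector",
    "TrainedModel",
    "Candidate",
    "featurize",
    "build_vocabulary",
    "train_models",
    "score_sentence",
    "rank_candidates",
]

FUNDING_ELEMENTS = frozenset({"funding_organization_name", "funding_number"})

_WORD = re.compile(r"[a-z0-9%]+(?:[-/'][a-z0-9%]+)*")


def _tokens(text: str) -> List[str]:
    return _WORD.findall(text.lower())


def featurize(sentence: Sentence, vocabulary: Optional[Dict[str, int]] = None):
    """Bag-of-terms counts for a sentence; unseen terms dropped when a
    vocabulary is supplied.

    Returns a ``Counter`` over term strings (no vocabulary) or over term
    indices (with vocabulary).
    """
    counts: Counter = Counter()
    toks = _tokens(sentence.text)
    counts.update(toks)
    counts.update(" ".join(p) for p in zip(toks, toks[1:]))
    counts.update(" ".join(p) for p in zip(toks, toks[1:], toks[2:]))
    counts.update(f"TAG_{e.kind}" for e in sentence.entities)
    for heading in sentence.section_path:
        norm = "_".join(_tokens(heading))
        if norm:
            counts[f"SEC_{norm}"] += 1
    if sentence.post_reference_flag:
        counts["TAG_post_reference"] += 1
    if vocabulary is None:
        return counts
    return Counter(
        {vocabulary[t]: c for t, c in counts.items() if t in vocabulary}
    )


#: alias used in type signatures: sparse mapping term -> count
FeatureVector = Counter


def build_vocabulary(
    docs: Sequence[AnnotatedDocument], min_df: int = 2
) -> Dict[str, int]:
    """Shared term index over a corpus; terms in fewer than ``min_df``
    sentences are dropped."""
    df: Counter = Counter()
    for doc in docs:
        for sent in doc.sentences:
            df.update(set(featurize(sent)))
    terms = sorted(t for t, c in df.items() if c >= min_df)
    return {t: i for i, t in enumerate(terms)}


def _matrix(
    sentences: Sequence[Sentence], vocabulary: Dict[str, int]
) -> sparse.csr_matrix:
    data, indices, indptr = [], [], [0]
    for sent in sentences:
        fv = featurize(sent, vocabulary)
        for idx in sorted(fv):
            indices.append(idx)
            data.append(fv[idx])
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(sentences), len(vocabulary)),
    )


@dataclass
class _NodeModel:
    weights: np.ndarray  # dense, over vocabulary
    bias: float
    platt_a: float
    platt_b: float

    def prob(self, X: sparse.csr_matrix) -> np.ndarray:
        margin = X @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-(self.platt_a * margin + self.platt_b)))


@dataclass
class TrainedModel:
    vocabulary: Dict[str, int]
    nodes: Dict[str, Optional[_NodeModel]]  # None = untrainable
    paths: Dict[str, Tuple[str, ...]]  # leaf -> root..leaf
    flat: bool = False
    metadata: Dict[str, object] = field(default_factory=dict)
    _doc_cache: Dict[str, sparse.csr_matrix] = field(default_factory=dict, repr=False)

    # -- scoring ------------------------------------------------------------

    def doc_matrix(self, doc: AnnotatedDocument) -> sparse.csr_matrix:
        X = self._doc_cache.get(doc.doc_id)
        if X is None or X.shape[0] != len(doc.sentences):
            X = _matrix(doc.sentences, self.vocabulary)
            self._doc_cache.clear()
            self._doc_cache[doc.doc_id] = X
        return X

    def element_scores(self, doc: AnnotatedDocument, element_id: str) -> np.ndarray:
        """Hierarchical confidence of every sentence for one element."""
        if element_id not in self.paths:
            raise SchemaError(f"unknown or non-classifier element {element_id!r}")
        X = self.doc_matrix(doc)
        scores = np.ones(X.shape[0])
        path = self.paths[element_id][1:]  # root excluded
        if self.flat:
            path = path[-1:]
        for node in path:
            nm = self.nodes.get(node)
            if nm is not None:
                scores *= nm.prob(X)
        return scores

    # -- persistence ----------------------------------------------------------

    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        terms = sorted(self.vocabulary, key=self.vocabulary.get)
        (d / "vocabulary.json").write_text(
            json.dumps(terms, ensure_ascii=False), encoding="utf-8"
        )
        nodes_payload = {}
        for name in sorted(self.nodes):
            nm = self.nodes[name]
            nodes_payload[name] = None if nm is None else {
                "weights": nm.weights.tolist(),
                "bias": nm.bias,
                "platt_a": nm.platt_a,
                "platt_b": nm.platt_b,
            }
        (d / "nodes.json").write_text(json.dumps(nodes_payload, sort_keys=True))
        meta = dict(self.metadata)
        meta["flat"] = self.flat
        meta["paths"] = {k: list(v) for k, v in sorted(self.paths.items())}
        (d / "metadata.json").write_text(json.dumps(meta, sort_keys=True, indent=1))

    @classmethod
    def load(cls, model_dir) -> "TrainedModel":
        d = Path(model_dir)
        terms = json.loads((d / "vocabulary.json").read_text(encoding="utf-8"))
        vocabulary = {t: i for i, t in enumerate(terms)}
        nodes_payload = json.loads((d / "nodes.json").read_text())
        nodes: Dict[str, Optional[_NodeModel]] = {}
        for name, nm in nodes_payload.items():
            nodes[name] = None if nm is None else _NodeModel(
                weights=np.asarray(nm["weights"], dtype=np.float64),
                bias=nm["bias"],
                platt_a=nm["platt_a"],
                platt_b=nm["platt_b"],
            )
        meta = json.loads((d / "metadata.json").read_text())
        paths = {k: tuple(v) for k, v in meta.pop("paths").items()}
        flat = meta.pop("flat", False)
        return cls(
            vocabulary=vocabulary, nodes=nodes, paths=paths, flat=flat, metadata=meta
        )


@dataclass
class Candidate:
    """One ranked candidate sentence for an element."""

    sentence_index: int
    text: str
    base_score: float
    final_score: float
    fragments: Tuple[Tuple[int, int], ...] = ()


def _platt(margins: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Monotone sigmoid calibration of decision margins (1-D logistic fit)."""
    lr = LogisticRegression(C=1e3, solver="lbfgs", max_iter=1000)
    lr.fit(margins.reshape(-1, 1), y)
    a = float(lr.coef_[0, 0])
    b = float(lr.intercept_[0])
    if a <= 0:  # calibration must not invert the margin ordering
        a, b = 1.0, 0.0
    return a, b


def train_models(
    corpus: Sequence[AnnotatedDocument],
    gold: Sequence[GoldAnnotation],
    specs: Sequence[ElementSpec],
    hierarchy: ElementHierarchy,
    seed: int = 0,
    C: float = 1.0,
    flat: bool = False,
    min_df: int = 2,
    class_weight: str = "balanced",
) -> TrainedModel:
    """Fit one classifier per hierarchy node from gold-annotated documents."""
    gold_by_doc = {g.doc_id: g for g in gold}
    missing = [d.doc_id for d in corpus if d.doc_id not in gold_by_doc]
    if missing:
        raise ValueError(f"no gold annotations for documents: {missing[:5]}")

    vocabulary = build_vocabulary(corpus, min_df=min_df)
    all_sentences: List[Sentence] = []
    sent_key: Dict[Tuple[str, int], int] = {}
    for doc in corpus:
        for sent in doc.sentences:
            sent_key[(doc.doc_id, sent.index)] = len(all_sentences)
            all_sentences.append(sent)
    X = _matrix(all_sentences, vocabulary)

    leaf_positives: Dict[str, set] = {}
    for doc in corpus:
        g = gold_by_doc[doc.doc_id]
        for eid, answers in g.answers.items():
            if eid in CITATION_ELEMENTS:
                continue
            rows = leaf_positives.setdefault(eid, set())
            for a in answers:
                rows.add(sent_key[(doc.doc_id, a.sentence_index)])

    def node_positives(node: str) -> set:
        kids = hierarchy.children.get(node)
        if kids is None:
            return leaf_positives.get(node, set())
        out: set = set()
        for k in kids:
            out |= node_positives(k)
        return out

    nodes: Dict[str, Optional[_NodeModel]] = {}
    untrainable: List[str] = []
    for node in hierarchy.nodes:
        if node == ROOT:
            continue
        pos = node_positives(node)
        if not pos or len(pos) == X.shape[0]:
            nodes[node] = None
            untrainable.append(node)
            continue
        y = np.zeros(X.shape[0], dtype=np.int8)
        y[sorted(pos)] = 1
        svm = LinearSVC(
            C=C, class_weight=class_weight, random_state=seed, max_iter=10000
        )
        svm.fit(X, y)
        margins = X @ svm.coef_.ravel() + float(svm.intercept_[0])
        a, b = _platt(margins, y)
        nodes[node] = _NodeModel(
            weights=svm.coef_.ravel().astype(np.float64),
            bias=float(svm.intercept_[0]),
            platt_a=a,
            platt_b=b,
        )

    paths = {
        s.element_id: s.hierarchy_path
        for s in specs
        if s.element_id not in CITATION_ELEMENTS
    }
    vocab_hash = hashlib.sha256(
        "\x00".join(sorted(vocabulary)).encode("utf-8")
    ).hexdigest()[:16]
    meta = {
        "seed": seed,
        "C": C,
        "min_df": min_df,
        "class_weight": class_weight,
        "n_documents": len(corpus),
        "n_sentences": int(X.shape[0]),
        "vocabulary_hash": vocab_hash,
        "untrainable_nodes": sorted(untrainable),
    }
    return TrainedModel(
        vocabulary=vocabulary, nodes=nodes, paths=paths, flat=flat, metadata=meta
    )


def score_sentence(model: TrainedModel, sentence: Sentence, element_id: str) -> float:
    """Hierarchical confidence of a single sentence for one element."""
    if element_id not in model.paths:
        raise SchemaError(f"unknown or non-classifier element {element_id!r}")
    X = _matrix([sentence], model.vocabulary)
    score = 1.0
    path = model.paths[element_id][1:]
    if model.flat:
        path = path[-1:]
    for node in path:
        nm = model.nodes.get(node)
        if nm is not None:
            score *= float(nm.prob(X)[0])
    return score


def rank_candidates(
    model: TrainedModel,
    doc: AnnotatedDocument,
    element_id: str,
    k: int = 5,
) -> List[Candidate]:
    """Top-k sentences by hierarchical confidence, decreasing; ties broken by
    earlier document position.  Post-reference sentences are eligible only
    for funding elements."""
    scores = model.element_scores(doc, element_id)
    eligible = [
        s.index
        for s in doc.sentences
        if (not s.post_reference_flag) or element_id in FUNDING_ELEMENTS
    ]
    order = sorted(eligible, key=lambda i: (-scores[i], i))[:k]
    return [
        Candidate(
            sentence_index=i,
            text=doc.sentences[i].text,
            base_score=float(scores[i]),
            final_score=float(scores[i]),
        )
        for i in order
    ]
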