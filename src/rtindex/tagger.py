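"""Optional trainable IOB2 sequence tagger for resource/criterion spans.

The deterministic pattern engine is the default detector; this module
preserves a trainable named-entity interface for users who have annotated
sentences of their own.  Tokens are labeled in IOB2 (``B-ANTIBODY``,
``I-ANTIBODY``, ``O``, ...) and the model is a per-token multinomial
logistic regression over lexical window features.  Training is fully
deterministic given the seed.

Annotated-sentence exchange format: CoNLL-style two-column text, one
``token<TAB>label`` pair per line, blank line between sentences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .types import Criterion, ResourceType

#: All legal IOB2 labels.
LABEL_TAXONOMY = frozenset(
    {"O"}
    | {f"{p}-{t.value}" for t in ResourceType for p in ("B", "I")}
    | {f"{p}-{c.value}" for c in Criterion for p in ("B", "I")}
)

AnnotatedSentence = Sequence[tuple[str, str]]


@dataclass
class TaggerModel:
    vectorizer: DictVectorizer
    classifier: LogisticRegression
    labels: tuple[str, ...]


def read_conll(text: str) -> list[list[tuple[str, str]]]:
    """Parse two-column token/label text into annotated sentences."""
    sentences: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for line in text.splitlines():
        if not line.strip():
            if current:
                sentences.append(current)
                current = []
            continue
        token, _, label = line.partition("\t")
        if not label:
            raise ValueError(f"malformed CoNLL line (no tab): {line!r}")
        current.append((token, label))
    if current:
        sentences.append(current)
    return sentences


def write_conll(sentences: Sequence[AnnotatedSentence]) -> str:
    blocks = ["\n".join(f"{tok}\t{lab}" for tok, lab in sent) for sent in sentences]
    return "\n\n".join(blocks) + "\n"


def _token_features(tokens: Sequence[str], i: int) -> dict[str, object]:
    tok = tokens[i]
    feats: dict[str, object] = {
        "word": tok,
        "lower": tok.lower(),
        "suffix3": tok[-3:].lower(),
        "prefix3": tok[:3].lower(),
        "is_upper": tok.isupper(),
        "is_title": tok.istitle(),
        "has_digit": any(ch.isdigit() for ch in tok),
        "has_hyphen": "-" in tok,
        "prev": tokens[i - 1].lower() if i > 0 else "<s>",
        "next": tokens[i + 1].lower() if i + 1 < len(tokens) else "</s>",
    }
    return feats


def train_tagger(annotated_sentences: Sequence[AnnotatedSentence], seed: int) -> TaggerModel:
    """Fit the token classifier on IOB2-annotated sentences.

    Raises ``ValueError`` on an empty training set or a label outside the
    taxonomy.
    """
    sentences = [list(s) for s in annotated_sentences if len(s) > 0]
    if not sentences:
        raise ValueError("empty training set")
    X: list[dict] = []
    y: list[str] = []
    for sent in sentences:
        tokens = [tok for tok, _ in sent]
        for i, (_, label) in enumerate(sent):
            if label not in LABEL_TAXONOMY:
                raise ValueError(f"label not in taxonomy: {label!r}")
            X.append(_token_features(tokens, i))
            y.append(label)
    vectorizer = DictVectorizer(sparse=True)
    Xv = vectorizer.fit_transform(X)
    clf = LogisticRegression(max_iter=500, random_state=seed)
    clf.fit(Xv, y)
    return TaggerModel(vectorizer=vectorizer, classifier=clf, labels=tuple(clf.classes_))


def tag(model: TaggerModel, sentence: str | Sequence[str]) -> list[str]:
    """Predict one IOB2 label per token (string input is split on space)."""
    tokens = sentence.split() if isinstance(sentence, str) else list(sentence)
    if not tokens:
        return []
    X = model.vectorizer.transform([_token_features(tokens, i) for i in range(len(tokens))])
    return list(model.classifier.predict(X))


def spans_from_labels(tokens: Sequence[str], labels: Sequence[str]) -> list[tuple[str, str]]:
    """Collapse IOB2 labels into (entity_label, surface_text) spans."""
    spans: list[tuple[str, str]] = []
    current_label = None
    current_tokens: list[str] = []
    for tok, lab in zip(tokens, labels):
        if lab.startswith("B-"):
            if current_label:
                spans.append((current_label, " ".join(current_tokens)))
            current_label = lab[2:]
            current_tokens = [tok]
        elif lab.startswith("I-") and current_label == lab[2:]:
            current_tokens.append(tok)
        else:
            if current_label:
                spans.append((current_label, " ".join(current_tokens)))
            current_label = None
            current_tokens = []
    if current_label:
        spans.append((current_label, " ".join(current_tokens)))
    return spans
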