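"""End-to-end gene-mention tagging pipeline as one estimator.

:class:`GeneMentionTagger` wires together preprocessing, feature
extraction, optional PCA feature selection, bidirectional CRF training with
the chosen integration mode, and rule-based post-processing.  It consumes
and produces the corpus-level objects (:class:`RawSentence`,
:class:`GeneMention`), so training and tagging mirror how the corpus files
are organized.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Sequence

from sklearn.base import BaseEstimator

from .corpus import (
    GeneMention,
    RawSentence,
    bio_to_mentions,
    group_by_sentence,
    mentions_to_bio,
)
from .crf import CrfModel
from .combine import BidirectionalTagger
from .features import (
    FeatureExtractor,
    FeatureExtractorConfig,
    FrequencyTable,
    occurrence_matrix,
    pca_select,
)
from .postprocess import (
    KeywordLexicon,
    PostKeywordList,
    build_pkl,
    postprocess_labels,
)
from .preprocess import DefaultBackend, preprocess_sentence


class GeneMentionTagger(BaseEstimator):
    """Trainable gene/protein mention tagger.

    Parameters mirror the method's tunable settings: ``theta_freq`` bounds
    the corpus-frequency band (default 10), ``pkl_min_count`` is the
    post-keyword-list threshold (default 3, "three or more times"),
    ``mode`` selects the integration strategy, ``mira_epochs`` the number
    of MIRA refinement passes.  ``pca_components``/``pca_keep`` switch on
    PCA-based feature selection when both are set.
    """

    def __init__(
        self,
        mode: str = "mira",
        theta_freq: int = 10,
        pkl_min_count: int = 3,
        ngram_window: int = 4,
        ngram_mode: str = "window",
        conjunction_offsets: tuple[int, ...] = (-2, -1, 1, 2),
        c2: float = 1.0,
        max_iter: int = 100,
        mira_epochs: int = 5,
        pca_components: int | None = None,
        pca_keep: int | None = None,
        postprocess: bool = True,
        lexicon: KeywordLexicon | None = None,
        backend=None,
    ) -> None:
        self.mode = mode
        self.theta_freq = theta_freq
        self.pkl_min_count = pkl_min_count
        self.ngram_window = ngram_window
        self.ngram_mode = ngram_mode
        self.conjunction_offsets = conjunction_offsets
        self.c2 = c2
        self.max_iter = max_iter
        self.mira_epochs = mira_epochs
        self.pca_components = pca_components
        self.pca_keep = pca_keep
        self.postprocess = postprocess
        self.lexicon = lexicon
        self.backend = backend

    # -- internals ------------------------------------------------------------

    def _extractor(self) -> FeatureExtractor:
        return FeatureExtractor(
            FeatureExtractorConfig(
                ngram_window=self.ngram_window,
                ngram_mode=self.ngram_mode,
                conjunction_offsets=tuple(self.conjunction_offsets),
                theta_freq=self.theta_freq,
            )
        )

    def _preprocess(self, sentences: Sequence[RawSentence]):
        backend = self.backend or DefaultBackend()
        return [preprocess_sentence(s, backend) for s in sentences]

    # -- estimator API --------------------------------------------------------

    def fit(
        self,
        sentences: Sequence[RawSentence],
        mentions: Sequence[GeneMention],
    ) -> "GeneMentionTagger":
        tokenized = self._preprocess(sentences)
        grouped = group_by_sentence(mentions)
        labels = [
            mentions_to_bio(ts, grouped.get(ts.sentence_id, [])) for ts in tokenized
        ]
        self.freq_table_ = FrequencyTable.build(mentions, self.theta_freq)
        self.pkl_ = build_pkl(mentions, self.pkl_min_count)
        extractor = self._extractor()
        X = [extractor.extract(ts, self.freq_table_) for ts in tokenized]

        self.selected_features_ = None
        if self.pca_components is not None and self.pca_keep is not None:
            matrix, names = occurrence_matrix(X)
            kept, eigenvalues = pca_select(
                matrix, names, self.pca_components, self.pca_keep
            )
            self.selected_features_ = frozenset(kept)
            self.pca_eigenvalues_ = eigenvalues
            keep = self.selected_features_
            X = [[fs & keep for fs in sent] for sent in X]

        self.tagger_ = BidirectionalTagger(
            mode=self.mode,
            c2=self.c2,
            max_iter=self.max_iter,
            mira_epochs=self.mira_epochs,
        ).fit(X, labels)
        return self

    def predict_labels(
        self, sentences: Sequence[RawSentence], mode: str | None = None
    ) -> tuple[list, list[list[str]]]:
        """Tokenized sentences and their post-processed label sequences."""
        tokenized = self._preprocess(sentences)
        extractor = self._extractor()
        X = [extractor.extract(ts, self.freq_table_) for ts in tokenized]
        if self.selected_features_ is not None:
            keep = self.selected_features_
            X = [[fs & keep for fs in sent] for sent in X]
        labels = self.tagger_.predict(X, mode=mode)
        if self.postprocess:
            labels = [
                postprocess_labels(ts, labs, self.lexicon, self.pkl_)
                for ts, labs in zip(tokenized, labels)
            ]
        return tokenized, labels

    def predict(
        self, sentences: Sequence[RawSentence], mode: str | None = None
    ) -> list[GeneMention]:
        tokenized, labels = self.predict_labels(sentences, mode=mode)
        out: list[GeneMention] = []
        for ts, labs in zip(tokenized, labels):
            out.extend(bio_to_mentions(ts, labs))
        return out

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted pipeline (models, tables, config) as JSON."""
        payload = {
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
                if k not in ("lexicon", "backend")
            },
            "freq_counts": dict(self.freq_table_.counts),
            "pkl_counts": dict(self.pkl_.counts),
            "selected_features": (
                sorted(self.selected_features_)
                if self.selected_features_ is not None
                else None
            ),
            "models": {},
        }
        t = self.tagger_
        if hasattr(t, "forward_"):
            payload["models"]["forward"] = json.loads(t.forward_.model_.to_json())
        if hasattr(t, "backward_"):
            payload["models"]["backward"] = json.loads(t.backward_.model_.to_json())
        if hasattr(t, "combined_"):
            payload["models"]["combined"] = json.loads(t.combined_.to_json())
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GeneMentionTagger":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        params = dict(payload["params"])
        params["conjunction_offsets"] = tuple(params["conjunction_offsets"])
        est = cls(**params)
        est.freq_table_ = FrequencyTable(
            counts=Counter(payload["freq_counts"]), theta_freq=est.theta_freq
        )
        est.pkl_ = PostKeywordList(
            Counter(payload["pkl_counts"]), est.pkl_min_count
        )
        est.selected_features_ = (
            frozenset(payload["selected_features"])
            if payload["selected_features"] is not None
            else None
        )
        tagger = BidirectionalTagger(
            mode=est.mode, c2=est.c2, max_iter=est.max_iter,
            mira_epochs=est.mira_epochs,
        )
        from .crf import CrfTagger

        models = payload["models"]
        if "forward" in models:
            sub = CrfTagger(direction="forward", c2=est.c2, max_iter=est.max_iter)
            sub.model_ = CrfModel.from_json(json.dumps(models["forward"]))
            tagger.forward_ = sub
        if "backward" in models:
            sub = CrfTagger(direction="backward", c2=est.c2, max_iter=est.max_iter)
            sub.model_ = CrfModel.from_json(json.dumps(models["backward"]))
            tagger.backward_ = sub
        if "combined" in models:
            tagger.combined_ = CrfModel.from_json(json.dumps(models["combined"]))
        est.tagger_ = tagger
        return est
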