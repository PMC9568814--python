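"""Context-window topic coherence (the c_v family).

Coherence of a topic's top words is the mean indirect cosine confirmation:
each word is represented by its vector of normalized pointwise mutual
information (NPMI) values against every top word, and is compared with the
summed vector of the whole set. Occurrence probabilities come from boolean
windows over the corpus; microblog documents are far shorter than the
conventional 110-token window, so each document is exactly one window and
probabilities reduce to document frequencies.
"""

from __future__ import annotations

import numpy as np


def _window_occurrence(doc_token_sets: list[set[str]], words: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Single and joint window-occurrence counts for the given word list."""
    n = len(words)
    index = {w: i for i, w in enumerate(words)}
    single = np.zeros(n)
    joint = np.zeros((n, n))
    for doc in doc_token_sets:
        present = [index[w] for w in doc if w in index]
        if not present:
            continue
        idx = np.array(present)
        single[idx] += 1
        joint[np.ix_(idx, idx)] += 1
    return single, joint


def _npmi_matrix(single: np.ndarray, joint: np.ndarray, n_windows: int, eps: float = 1e-12) -> np.ndarray:
    p_single = single / n_windows
    p_joint = joint / n_windows
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((p_joint + eps) / np.outer(p_single, p_single))
        npmi = pmi / -np.log(p_joint + eps)
    npmi[~np.isfinite(npmi)] = 0.0
    np.fill_diagonal(npmi, 1.0)
    npmi[single == 0, :] = 0.0
    npmi[:, single == 0] = 0.0
    return npmi


def cv_coherence(
    doc_token_sets: list[set[str]], topic_top_words: list[list[str]]
) -> float:
    """Mean c_v coherence over topics, each given as its top-word list."""
    n_windows = len(doc_token_sets)
    if n_windows == 0:
        raise ValueError("empty corpus")
    scores = []
    for words in topic_top_words:
        words = list(dict.fromkeys(words))
        if len(words) < 2:
            continue
        single, joint = _window_occurrence(doc_token_sets, words)
        npmi = _npmi_matrix(single, joint, n_windows)
        v_all = npmi.sum(axis=0)
        phis = []
        for i in range(len(words)):
            if single[i] == 0:
                continue
            v_i = npmi[i]
            denom = np.linalg.norm(v_i) * np.linalg.norm(v_all)
            if denom == 0:
                continue
            phis.append(float(v_i @ v_all / denom))
        if phis:
            scores.append(float(np.mean(phis)))
    if not scores:
        raise ValueError("no scorable topic (top words never occur in the corpus)")
    return float(np.mean(scores))
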