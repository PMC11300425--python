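"""Cross-validation fold construction.

Five repetitions by default: in each one, three folds train, one validates
and one tests, so every case appears in exactly one test set across the
five repetitions (train:val:test = 3:1:1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FoldSplit:
    """One cross-validation repetition."""

    train: list
    val: list
    test: list

    def all_ids(self) -> set:
        return set(self.train) | set(self.val) | set(self.test)


def make_cv_splits(
    case_ids,
    n_folds: int = 5,
    seed: int = 0,
    stratify_labels=None,
) -> list[FoldSplit]:
    """Partition ``case_ids`` into ``n_folds`` folds and rotate them.

    Repetition ``r`` uses fold ``r`` as test, fold ``(r+1) mod n_folds`` as
    validation and the remaining folds as training.  With
    ``stratify_labels`` (one hashable label per case, e.g. healthy vs
    pathological) the folds balance each label via round-robin assignment
    after a seeded shuffle.
    """
    ids = list(case_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} cases, got {len(ids)}")
    rng = np.random.default_rng(seed)

    folds: list[list] = [[] for _ in range(n_folds)]
    if stratify_labels is None:
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            folds[pos % n_folds].append(ids[idx])
    else:
        labels = list(stratify_labels)
        if len(labels) != len(ids):
            raise ValueError("stratify_labels must match case_ids in length")
        offset = 0
        for lab in sorted(set(map(repr, labels))):
            members = [i for i, l in zip(ids, labels) if repr(l) == lab]
            order = rng.permutation(len(members))
            for pos, idx in enumerate(order):
                folds[(offset + pos) % n_folds].append(members[idx])
            offset += len(members)

    splits = []
    for r in range(n_folds):
        test = folds[r]
        val = folds[(r + 1) % n_folds]
        train = [c for i, f in enumerate(folds) if i not in (r, (r + 1) % n_folds)
                 for c in f]
        splits.append(FoldSplit(train=train, val=val, test=test))
    return splits
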