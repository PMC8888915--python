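"""Per-sample alpha diversity: Hill numbers and Faith's phylogenetic diversity.

Hill number of order q is the "effective number of equally common taxa":
order 0 is plain richness, order 1 is exp(Shannon entropy) (natural log
inside; the exponential makes the base immaterial). Faith's PD is the sum
of branch lengths of the tree subtree spanning the observed taxa; the
default convention is root-inclusive (union of leaf-to-root paths), with
an unrooted variant that drops the stem above the observed clade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio

from .containers import CountMatrix


def hill_diversity(sample_counts, order: int) -> float:
    """Hill diversity ^qD of one sample for q in {0, 1}.

    Order 0 counts taxa with positive abundance; order 1 is
    exp(-sum p_i ln p_i) over positive counts, with p_i = count_i / total.
    """
    x = np.asarray(sample_counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero sample: diversity undefined")
    if order == 0:
        return float(x.size)
    if order == 1:
        p = x / x.sum()
        return float(np.exp(-np.sum(p * np.log(p))))
    raise ValueError(f"unsupported Hill order {order!r} (only 0 and 1)")


def faith_pd(
    sample_counts,
    taxon_ids: list[str],
    tree: skbio.TreeNode,
    strict: bool = True,
    include_root: bool = True,
) -> float:
    """Faith's PD of one sample on a rooted tree with branch lengths.

    Presence-only: a taxon is observed iff its count is positive. With
    ``include_root`` (default) PD is the total length of the union of the
    observed leaves' root paths; otherwise the stem above the most recent
    common ancestor of the observed set is excluded.

    With ``strict`` (default) an observed taxon missing from the tree is an
    error; otherwise the observed set is intersected with the leaf set.
    """
    x = np.asarray(sample_counts, dtype=float)
    if len(taxon_ids) != x.size:
        raise ValueError("taxon_ids length does not match counts")
    observed = {t for t, c in zip(taxon_ids, x) if c > 0}
    if not observed:
        raise ValueError("no observed taxa: PD undefined")
    leaf_names = {tip.name for tip in tree.tips()}
    missing = sorted(observed - leaf_names)
    if missing:
        if strict:
            raise KeyError(f"observed taxa missing from tree: {missing}")
        observed -= set(missing)
        if not observed:
            raise ValueError("no observed taxa present in tree")

    # postorder sweep: a branch is in the spanning set iff its subtree
    # contains at least one observed leaf
    n_below: dict[int, int] = {}
    pd_sum = 0.0
    stem_sum = 0.0  # branches whose subtree holds *all* observed leaves
    n_obs = len(observed)
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            cnt = 1 if node.name in observed else 0
        else:
            cnt = sum(n_below[id(child)] for child in node.children)
        n_below[id(node)] = cnt
        if node is tree:
            continue
        if cnt > 0:
            length = node.length or 0.0
            pd_sum += length
            if cnt == n_obs:
                stem_sum += length
    if include_root:
        return float(pd_sum)
    return float(pd_sum - stem_sum)


def diversity_table(
    matrix: CountMatrix,
    tree: skbio.TreeNode | None = None,
    strict_tree: bool = True,
    include_root: bool = True,
) -> pd.DataFrame:
    """One diversity record per sample: richness (^0D), ^1D, and Faith PD.

    The ``faith_pd`` column is absent when no tree is supplied.
    """
    records = []
    for j, sample_id in enumerate(matrix.sample_ids):
        col = matrix.counts[:, j]
        rec = {
            "sample_id": sample_id,
            "richness": int(hill_diversity(col, 0)),
            "hill1": hill_diversity(col, 1),
        }
        if tree is not None:
            rec["faith_pd"] = faith_pd(
                col, matrix.taxon_ids, tree, strict=strict_tree, include_root=include_root
            )
        records.append(rec)
    return pd.DataFrame(records)
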