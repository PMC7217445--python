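"""Grouped (per-choice-situation) softmax/log-sum-exp helpers.

Rows of a long-format dataset are grouped into contiguous situations;
``starts`` holds the first row index of each situation.  All routines use
max-subtraction so utilities may be arbitrarily large without overflow.
"""

from __future__ import annotations

import numpy as np


def situation_starts(df, keys=("respondent_id", "situation_id")):
    """Start offsets and lengths of contiguous (respondent, situation) groups.

    The frame must already be grouped contiguously (the canonical sort);
    raises if a group reappears after a different one.
    """
    ids = df[list(keys)].astype(str).agg("\x1f".join, axis=1).to_numpy()
    change = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    if len(np.unique(ids)) != len(change):
        raise ValueError("situations are not contiguous; sort by respondent and situation")
    lengths = np.diff(np.r_[change, len(ids)])
    return change, lengths


def _uniform_length(lengths):
    L = int(lengths[0])
    return L if (lengths == L).all() else None


def segment_logsumexp(u, starts, lengths):
    """Log-sum-exp of ``u`` (rows x ...) within each contiguous segment.

    Equal-length segments take a reshape-based fast path; ragged segments
    fall back to ufunc.reduceat.
    """
    L = _uniform_length(lengths)
    if L is not None:
        v = u.reshape(len(starts), L, *u.shape[1:])
        m = v.max(axis=1)
        s = np.exp(v - np.expand_dims(m, 1)).sum(axis=1)
        return m + np.log(s)
    m = np.maximum.reduceat(u, starts, axis=0)
    e = np.exp(u - np.repeat(m, lengths, axis=0))
    s = np.add.reduceat(e, starts, axis=0)
    return m + np.log(s)


def segment_softmax(u, starts, lengths):
    """Per-row softmax within each contiguous segment; columns are independent."""
    L = _uniform_length(lengths)
    if L is not None:
        v = u.reshape(len(starts), L, *u.shape[1:])
        m = np.expand_dims(v.max(axis=1), 1)
        e = np.exp(v - m)
        e /= e.sum(axis=1, keepdims=True)
        return e.reshape(u.shape)
    m = np.maximum.reduceat(u, starts, axis=0)
    e = np.exp(u - np.repeat(m, lengths, axis=0))
    s = np.add.reduceat(e, starts, axis=0)
    return e / np.repeat(s, lengths, axis=0)


def segment_sum(v, starts):
    return np.add.reduceat(v, starts, axis=0)
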