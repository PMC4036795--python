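"""Reconciliation of new gene models against a prior annotation.

Models are paired by same-strand genomic overlap of at least 1 nt; connected
components of the resulting bipartite graph are classified into correction
events (confirmed, boundary change, split, merge, novel, unsupported).
Every prior and every new ID lands in exactly one event.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .model import CorrectionEvent, GeneModel, RenscanError


def _check_unique(models: Sequence[GeneModel], label: str) -> None:
    seen = set()
    for m in models:
        if m.gene_id in seen:
            raise RenscanError(f"duplicate ID {m.gene_id!r} in {label} set")
        seen.add(m.gene_id)


def reconcile(
    prior_models: Sequence[GeneModel],
    new_models: Sequence[GeneModel],
    params=None,
) -> list[CorrectionEvent]:
    """Pair prior and new models by same-strand overlap and emit one
    correction event per connected component.

    1-to-1 with identical bounds -> confirmed; 1-to-1 differing -> boundary;
    one prior over k>=2 new -> split (the prior was a fusion); k>=2 prior
    under one new -> merge; unmatched new -> novel; unmatched prior ->
    unsupported.  Many-to-many components are emitted as a single boundary
    event flagged for manual review.  Events are sorted by genomic position.
    """
    _check_unique(prior_models, "prior")
    _check_unique(new_models, "new")

    # sweep per (seq_id, strand) to find overlapping pairs
    adj_p: dict[str, set] = defaultdict(set)
    adj_n: dict[str, set] = defaultdict(set)
    by_key: dict[tuple, list] = defaultdict(list)
    for side, models in (("p", prior_models), ("n", new_models)):
        for m in models:
            by_key[(m.seq_id, m.strand)].append((side, m))
    for items in by_key.values():
        items.sort(key=lambda x: x[1].start)
        active: list = []
        for side, m in items:
            active = [(s2, m2) for s2, m2 in active if m2.end > m.start]
            for s2, m2 in active:
                if s2 != side:
                    p, n = (m2, m) if s2 == "p" else (m, m2)
                    adj_p[p.gene_id].add(n.gene_id)
                    adj_n[n.gene_id].add(p.gene_id)
            active.append((side, m))

    prior_by_id = {m.gene_id: m for m in prior_models}
    new_by_id = {m.gene_id: m for m in new_models}

    events: list[CorrectionEvent] = []
    visited_p: set = set()
    visited_n: set = set()

    def component(seed_side: str, seed_id: str) -> tuple[list, list]:
        ps, ns = [], []
        stack = [(seed_side, seed_id)]
        while stack:
            side, gid = stack.pop()
            if side == "p":
                if gid in visited_p:
                    continue
                visited_p.add(gid)
                ps.append(gid)
                stack.extend(("n", x) for x in adj_p[gid])
            else:
                if gid in visited_n:
                    continue
                visited_n.add(gid)
                ns.append(gid)
                stack.extend(("p", x) for x in adj_n[gid])
        return sorted(ps), sorted(ns)

    def span_of(ps, ns):
        ms = [prior_by_id[i] for i in ps] + [new_by_id[i] for i in ns]
        return ms[0].seq_id, (min(m.start for m in ms), max(m.end for m in ms))

    for m in prior_models:
        if m.gene_id in visited_p:
            continue
        ps, ns = component("p", m.gene_id)
        seq_id, span = span_of(ps, ns)
        if not ns:
            etype, review = "unsupported", False
        elif len(ps) == 1 and len(ns) == 1:
            n = new_by_id[ns[0]]
            same = (n.start, n.end) == (m.start, m.end)
            etype, review = ("confirmed" if same else "boundary"), False
        elif len(ps) == 1:
            etype, review = "split", False
        elif len(ns) == 1:
            etype, review = "merge", False
        else:
            etype, review = "boundary", True   # many-to-many: manual review
        events.append(CorrectionEvent(etype, ps, ns, seq_id, span, review))
    for m in new_models:
        if m.gene_id in visited_n:
            continue
        ps, ns = component("n", m.gene_id)
        seq_id, span = span_of(ps, ns)
        events.append(CorrectionEvent("novel", ps, ns, seq_id, span))
    events.sort(key=lambda e: (e.seq_id, e.span))
    return events


def write_event_table(events: Sequence[CorrectionEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_type\tprior_ids\tnew_ids\tseq_id\tspan\tneeds_review\n")
        for e in events:
            fh.write("\t".join([
                e.event_type,
                ",".join(e.prior_ids) or "-",
                ",".join(e.new_ids) or "-",
                e.seq_id,
                f"{e.span[0]}-{e.span[1]}",
                "yes" if e.needs_review else "no",
            ]) + "\n")
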