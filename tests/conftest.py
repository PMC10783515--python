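import pytest

from muxtalk.netbuild import (
    EdgeRecord,
    SignalingMultigraph,
    build_multilayer,
)


def make_multigraph(edges, extra_nodes=(), kinds=None):
    """Multigraph from (source, target, type, directed[, pathway]) tuples."""
    records = []
    for e in edges:
        src, tgt, itype, directed = e[:4]
        pathway = e[4] if len(e) > 4 else "pw1"
        records.append(EdgeRecord(src, tgt, itype, directed, pathway))
    nodes = {r.source for r in records} | {r.target for r in records} | set(extra_nodes)
    node_kinds = {n: "gene" for n in nodes}
    if kinds:
        node_kinds.update(kinds)
    return SignalingMultigraph(nodes=nodes, edges=records, node_kinds=node_kinds)


def make_net(sig_edges, grn_edges, ppi_edges=(), extra_nodes=(), membership=None):
    """Small multilayer network from explicit edge tuples.

    ``sig_edges``: (source, target, type, directed[, pathway]); ``grn_edges``:
    (tf, target); ``ppi_edges``: unordered (a, b) merged via refinement.
    """
    from muxtalk.netbuild import refine_signaling

    mg = make_multigraph(sig_edges, extra_nodes=extra_nodes)
    refined = refine_signaling(mg, ppi_edges)
    return build_multilayer(refined, grn_edges, membership=membership)


@pytest.fixture
def net_factory():
    return make_net


@pytest.fixture(scope="session")
def synth_net():
    """One deterministic mid-size synthetic network shared across tests."""
    from muxtalk.synthgen import SynthSpec, gen_multilayer

    net, members = gen_multilayer(SynthSpec(seed=11))
    return net, members
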