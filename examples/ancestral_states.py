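"""Ancestral state reconstruction of style shape on the Potentilla fixture.

Fits the three Mk parameterizations (ER one shared rate, SYM one rate per
unordered state pair, ARD one per ordered pair) to the style-shape
character on the nuclear tree, picks a model by likelihood-ratio test, and
prints the scaled marginal likelihoods at a few deep nodes.

The fixture tree carries unit branch lengths (the published figures have
no usable lengths), so the reconstruction is qualitative: read the state
identities, not the probabilities.
"""

from phylodiscord import (
    fit_model,
    likelihood_ratio_test,
    marginal_asr,
    potentilla_fixture,
    resolve_polytomies,
)

fx = potentilla_fixture()
tree = resolve_polytomies(fx.nuclear)  # zero-length branches; logL unchanged
style = fx.character_matrix("style")  # L / N / G / C, '?' for missing

fits = {kind: fit_model(tree, style, kind) for kind in ("ER", "SYM", "ARD")}
for kind, fit in fits.items():
    print(f"{kind}: logL {fit.log_likelihood:.3f} ({len(fit.model.params)} rates)")

best = "ER"
for nested, general in (("ER", "SYM"), ("SYM", "ARD")):
    lrt = likelihood_ratio_test(fits[nested], fits[general])
    print(f"{nested} vs {general}: LR={lrt.statistic:.3f}, df={lrt.df}, p={lrt.p:.4f}")
    if lrt.p < 0.05 and best == nested:
        best = general
print(f"selected model: {best}\n")

asr = marginal_asr(tree, style, fits[best].model)
# in the nuclear tree P. norvegica sits with the ivesioids, outside Argentea
argentea = frozenset(fx.table[fx.table["clade"] == "F"]["taxon"]) - {
    "Potentilla_norvegica"
}
ivesioid = frozenset(fx.table[fx.table["clade"] == "E"]["taxon"])
for label, clade in [
    ("Argentea clade MRCA", argentea),
    ("ivesioid clade MRCA", ivesioid),
    ("ivesioid + P. norvegica", ivesioid | {"Potentilla_norvegica"}),
]:
    vec = asr.node_likelihoods[clade][0]
    states = ", ".join(f"{s}={p:.2f}" for s, p in zip(asr.alphabet, vec))
    print(f"{label}: {states}")

# Each line gives the scaled marginal likelihood of every style type at
# that ancestor; the four values sum to 1.  The Conostylae type (C)
# dominating the Argentea/ivesioid ancestors mirrors the predominance of
# cone-shaped styles in those clades.
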