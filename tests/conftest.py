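"""Shared fixtures: synthetic bundles at two scales and a full pipeline run.

The small bundle exercises every structural feature cheaply; the full-size
bundle (200 planted WRKY genes, 100 decoys) is the standard study design
used for end-to-end recovery checks.  Both are generated once per session.
"""

from __future__ import annotations

import pytest

from familyscope import pipeline, plan, synth


@pytest.fixture(scope="session")
def bundle_small(tmp_path_factory):
    spec = plan.default_spec(seed=11, n_wrky=30, n_decoys=20)
    return synth.generate(spec, tmp_path_factory.mktemp("bundle_small"))


@pytest.fixture(scope="session")
def bundle_full(tmp_path_factory):
    spec = plan.default_spec(seed=101)
    return synth.generate(spec, tmp_path_factory.mktemp("bundle_full"))


def run_pipeline(bundle, out_dir, **overrides):
    cfg = pipeline.PipelineConfig(
        proteome=str(bundle.proteome_path),
        genome=str(bundle.genome_path),
        gff3=str(bundle.gff3_path),
        references=str(bundle.references_path),
        reference_labels=str(bundle.reference_labels_path),
        fpkm=str(bundle.fpkm_path),
        out_dir=str(out_dir),
        seed=bundle.spec.seed,
        **overrides,
    )
    return pipeline.run_all(cfg)


@pytest.fixture(scope="session")
def result_small(bundle_small, tmp_path_factory):
    return run_pipeline(bundle_small, tmp_path_factory.mktemp("out_small"))


@pytest.fixture(scope="session")
def result_full(bundle_full, tmp_path_factory):
    return run_pipeline(bundle_full, tmp_path_factory.mktemp("out_full"))


def truth_element_hits(row) -> set[tuple[str, int, str]]:
    """Decode the truth table's element_hits column."""
    if row["element_hits"] == "-":
        return set()
    out = set()
    for tok in row["element_hits"].split(";"):
        name, offset, strand = tok.rsplit(":", 2)
        out.add((name, int(offset), strand))
    return out
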