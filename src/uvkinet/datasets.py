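"""Bundled reference fixtures from the chronic-UV mouse skin study.

Three small text resources ship with the package:

* the GO memberships reported for the 514 downregulated genes (GMT),
* the published top-50 candidate gene list (one id per line; unannotated
  probes appear as ``NA_*`` placeholders and one symbol is listed twice,
  exactly as published), and
* the published summary counts (DEG totals, cluster sizes, prediction
  pool size, optimal threshold).

Together they are sufficient to recompute every fold-enrichment and
percentage the study prints; the underlying expression matrix
(GSE58915) is not bundled and not required for that arithmetic.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .io_formats import GeneSetCollection, read_gene_list, read_gmt

_DATA = resources.files("uvkinet") / "data"


def load_down_gene_sets() -> GeneSetCollection:
    """GO sets annotated among the 514 downregulated genes."""
    with resources.as_file(_DATA / "photoaging_go_down.gmt") as p:
        return read_gmt(p)


def load_top50() -> list[str]:
    """Published top-50 candidate list, in ranked order (50 entries,
    including placeholders for unannotated probes and one repeated id)."""
    with resources.as_file(_DATA / "photoaging_top50.txt") as p:
        return read_gene_list(p)


def load_reported_counts() -> dict:
    """Published summary counts (see the YAML for provenance notes)."""
    with resources.as_file(_DATA / "photoaging_counts.yaml") as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def reported_enrichment_folds() -> dict[str, float]:
    """Recompute the study's four headline fold enrichments from the
    bundled memberships and counts (rounded to display precision).

    Keys: ``ecm_clusters46`` (matrix genes concentrating in the two
    week-2-recovery clusters), ``morphogenesis_top50``, ``ecm_top50``,
    ``polysaccharide_top50`` (top-50 list vs the 514-gene background).
    """
    from .enrichment import display_fold, fold_enrichment

    counts = load_reported_counts()
    sets = load_down_gene_sets()
    top50 = load_top50()
    top50_unique = set(top50)
    n_top, n_down = counts["top50_n"], counts["n_down"]

    out = {
        "ecm_clusters46": display_fold(fold_enrichment(
            counts["ecm_genes_in_clusters_4_6"], counts["clusters_4_6_size"],
            counts["ecm_genes_in_down"], n_down)),
    }
    for key, set_name in [
        ("morphogenesis_top50", "morphogenesis of an epithelium"),
        ("ecm_top50", "proteinaceous extracellular matrix"),
        ("polysaccharide_top50", "polysaccharide binding"),
    ]:
        members = set(sets[set_name].members)
        k = len(members & top50_unique)
        out[key] = display_fold(fold_enrichment(k, n_top, len(members), n_down))
    return out
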