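"""Full comparative pipeline on a synthetic three-species community.

Generates annotated genomes with a planted SOS-like regulon, builds the motif
from the planted sites, predicts and revises operons, and summarises regulon
conservation as a species x ortholog-group matrix ordered by the TF tree.
"""

from regulonscout import (CommunityConfig, build_motif, build_regulon_matrix,
                          evaluate_recovery, generate_community, predict_operons)

genomes, truth = generate_community(CommunityConfig(seed=0))
reference = genomes[0]
print("species:", [g.genome_id for g in genomes])
print("genes per genome:", len(reference.genes))
print("operons predicted in", reference.genome_id, ":",
      len(predict_operons(reference)))

motif = build_motif(list(truth.sites[truth.sites.role == "primary"].sequence))
matrix = build_regulon_matrix(genomes, reference, motif, tf_gene_id="sp01_lexA")
print("TF tree:", matrix.tf_tree_newick)
print()
print(matrix.to_tsv())

predicted = {(sp, gid.split("_", 1)[1])
             for sp, gid in matrix.regulated_pairs(0.5 * motif.max_score)}
score = evaluate_recovery(predicted, truth)
print(f"planted-regulon recovery: precision={score.precision:.2f} "
      f"recall={score.recall:.2f}")
# Rows for the planted regulon (lexA, recA, imuA-imuB-dnaE2, ...) score near
# 1.0 in every species; background rows sit near 0 or carry no credible site.
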