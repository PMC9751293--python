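"""Screen protein sequences for the glycine reductase (GrdB) signature.

Generates a small synthetic set - GrdB-bearing positives, GrdF-bearing
(sarcosine reductase) paralogs, and shuffled decoys - classifies every
sequence with the conserved-residue motifs, and clusters at 75%
identity.  GrdF takes precedence: any sequence (or cluster) carrying
the sarcosine-reductase signature is excluded from the GrdB set.
"""

import serplith as sp
from serplith.synth import SyntheticSeqSpec, generate_grd_sequences

records, truth = generate_grd_sequences(
    SyntheticSeqSpec(n_grdb=5, n_grdf=3, n_decoy=4, seed=7))

print(f"{'sequence':12s} {'truth':10s} {'label':10s} grdB  grdF")
truth_by_id = dict(truth)
for lab in sp.classify_grd(records):
    print(f"{lab.sequence_id:12s} {truth_by_id[lab.sequence_id]:10s} "
          f"{lab.label:10s} {str(lab.evidence['GrdB']):5s} "
          f"{str(lab.evidence['GrdF'])}")

clusters, cluster_labels = sp.classify_grd_clusters(records, threshold=0.75)
print(f"\n{len(clusters)} clusters at 75% identity "
      "(shuffled decoys and unrelated positives stay apart):")
for cl in clusters:
    print(f"  rep {cl.representative}: {len(cl.members)} member(s), "
          f"label {cluster_labels[cl.representative]}")
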