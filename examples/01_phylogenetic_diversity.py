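"""Faith's PD, MPD and MNTD on a small hand-checkable phylogeny.

The tree ((A:1,B:1):1,C:2); has total branch length 5.  A community holding
A and B spans their two unit branches plus the unit stem to the root, so its
PD is 3; the full community's MPD averages the three pairwise distances
(2, 4, 4) and its MNTD averages each species' nearest-neighbour distance
(2, 2, 4).
"""

import phylospat as ps

tree = ps.parse_newick("((A:1,B:1):1,C:2);")
D = ps.cophenetic_matrix(tree)

print("cophenetic distances:")
print(D.to_dataframe())
print()
print(f"PD(A,B)        = {ps.faith_pd(tree, ['A', 'B']):.4f}   (root-inclusive)")
print(f"PD(A,B) crown  = {ps.faith_pd(tree, ['A', 'B'], include_root=False):.4f}")
print(f"PD(A,B,C)      = {ps.faith_pd(tree, ['A', 'B', 'C']):.4f}   (= total branch length)")
print(f"MPD(A,B,C)     = {ps.mpd(D, ['A', 'B', 'C']):.4f}   (= (2+4+4)/3)")
print(f"MNTD(A,B,C)    = {ps.mntd(D, ['A', 'B', 'C']):.4f}   (= (2+2+4)/3)")
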