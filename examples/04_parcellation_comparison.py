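"""Compare two network-to-ROI parcellations with Jaccard indices.

Simulates a voxel-overlap table between an independent voxelwise network
decomposition and the ROI atlas (with 20% of each ROI's voxels spilling
into other networks), allocates each ROI to its majority network —
averaging bilateral pair counts first so homologs share an assignment —
and scores the agreement with the planted reference parcellation.
"""

import dogconn as dc

meta = dc.default_metadata(seed=1)
networks = dc.planted_networks_from_metadata(meta)
reference = dc.NetworkAssignment(
    {roi: net for net, rois in networks.items() for roi in rois}
)

overlap = dc.generate_overlap_table(meta, networks, jitter=0.2, seed=5)
assigned = dc.allocate_rois(overlap, meta)
print(f"allocated {len(assigned.mapping)} ROIs to {len(assigned.networks())} networks; "
      f"{len(assigned.unallocated)} unallocatable")

table = dc.match_networks(reference, assigned)
print("\nbest-partner Jaccard per reference network (1.0 = identical membership):")
print(table.to_string(index=False))
print("\nmean Jaccard:", round(table["jaccard"].mean(), 3))
print("Scores near 1 mean majority-vote allocation recovered the planted "
      "membership despite the simulated overlap spill.")
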