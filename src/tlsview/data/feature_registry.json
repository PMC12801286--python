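{
 "registry_version": "tlsview-226-v1",
 "n_features": 226,
 "distance_bin_right_edges_mm": [
  0.0,
  0.4,
  1.0,
  2.2,
  4.5,
  6.4
 ],
 "area_bin_right_edges_mm2": [
  0.03,
  0.05,
  0.07,
  0.1,
  0.15,
  0.28
 ],
 "names": [
  "dist0_Agg_count",
  "dist0_Agg_area_total",
  "dist0_Agg_area_mean",
  "dist1_Agg_count",
  "dist1_Agg_area_total",
  "dist1_Agg_area_mean",
  "dist2_Agg_count",
  "dist2_Agg_area_total",
  "dist2_Agg_area_mean",
  "dist3_Agg_count",
  "dist3_Agg_area_total",
  "dist3_Agg_area_mean",
  "dist4_Agg_count",
  "dist4_Agg_area_total",
  "dist4_Agg_area_mean",
  "dist5_Agg_count",
  "dist5_Agg_area_total",
  "dist5_Agg_area_mean",
  "dist6_Agg_count",
  "dist6_Agg_area_total",
  "dist6_Agg_area_mean",
  "dist0_FL1_count",
  "dist0_FL1_area_total",
  "dist0_FL1_area_mean",
  "dist1_FL1_count",
  "dist1_FL1_area_total",
  "dist1_FL1_area_mean",
  "dist2_FL1_count",
  "dist2_FL1_area_total",
  "dist2_FL1_area_mean",
  "dist3_FL1_count",
  "dist3_FL1_area_total",
  "dist3_FL1_area_mean",
  "dist4_FL1_count",
  "dist4_FL1_area_total",
  "dist4_FL1_area_mean",
  "dist5_FL1_count",
  "dist5_FL1_area_total",
  "dist5_FL1_area_mean",
  "dist6_FL1_count",
  "dist6_FL1_area_total",
  "dist6_FL1_area_mean",
  "dist0_FL2_count",
  "dist0_FL2_area_total",
  "dist0_FL2_area_mean",
  "dist1_FL2_count",
  "dist1_FL2_area_total",
  "dist1_FL2_area_mean",
  "dist2_FL2_count",
  "dist2_FL2_area_total",
  "dist2_FL2_area_mean",
  "dist3_FL2_count",
  "dist3_FL2_area_total",
  "dist3_FL2_area_mean",
  "dist4_FL2_count",
  "dist4_FL2_area_total",
  "dist4_FL2_area_mean",
  "dist5_FL2_count",
  "dist5_FL2_area_total",
  "dist5_FL2_area_mean",
  "dist6_FL2_count",
  "dist6_FL2_area_total",
  "dist6_FL2_area_mean",
  "area0_Agg_count",
  "area0_Agg_area_total",
  "area0_Agg_area_mean",
  "area1_Agg_count",
  "area1_Agg_area_total",
  "area1_Agg_area_mean",
  "area2_Agg_count",
  "area2_Agg_area_total",
  "area2_Agg_area_mean",
  "area3_Agg_count",
  "area3_Agg_area_total",
  "area3_Agg_area_mean",
  "area4_Agg_count",
  "area4_Agg_area_total",
  "area4_Agg_area_mean",
  "area5_Agg_count",
  "area5_Agg_area_total",
  "area5_Agg_area_mean",
  "area6_Agg_count",
  "area6_Agg_area_total",
  "area6_Agg_area_mean",
  "area0_FL1_count",
  "area0_FL1_area_total",
  "area0_FL1_area_mean",
  "area1_FL1_count",
  "area1_FL1_area_total",
  "area1_FL1_area_mean",
  "area2_FL1_count",
  "area2_FL1_area_total",
  "area2_FL1_area_mean",
  "area3_FL1_count",
  "area3_FL1_area_total",
  "area3_FL1_area_mean",
  "area4_FL1_count",
  "area4_FL1_area_total",
  "area4_FL1_area_mean",
  "area5_FL1_count",
  "area5_FL1_area_total",
  "area5_FL1_area_mean",
  "area6_FL1_count",
  "area6_FL1_area_total",
  "area6_FL1_area_mean",
  "area0_FL2_count",
  "area0_FL2_area_total",
  "area0_FL2_area_mean",
  "area1_FL2_count",
  "area1_FL2_area_total",
  "area1_FL2_area_mean",
  "area2_FL2_count",
  "area2_FL2_area_total",
  "area2_FL2_area_mean",
  "area3_FL2_count",
  "area3_FL2_area_total",
  "area3_FL2_area_mean",
  "area4_FL2_count",
  "area4_FL2_area_total",
  "area4_FL2_area_mean",
  "area5_FL2_count",
  "area5_FL2_area_total",
  "area5_FL2_area_mean",
  "area6_FL2_count",
  "area6_FL2_area_total",
  "area6_FL2_area_mean",
  "joint_d0_a0_count",
  "joint_d0_a1_count",
  "joint_d0_a2_count",
  "joint_d0_a3_count",
  "joint_d0_a4_count",
  "joint_d0_a5_count",
  "joint_d0_a6_count",
  "joint_d1_a0_count",
  "joint_d1_a1_count",
  "joint_d1_a2_count",
  "joint_d1_a3_count",
  "joint_d1_a4_count",
  "joint_d1_a5_count",
  "joint_d1_a6_count",
  "joint_d2_a0_count",
  "joint_d2_a1_count",
  "joint_d2_a2_count",
  "joint_d2_a3_count",
  "joint_d2_a4_count",
  "joint_d2_a5_count",
  "joint_d2_a6_count",
  "joint_d3_a0_count",
  "joint_d3_a1_count",
  "joint_d3_a2_count",
  "joint_d3_a3_count",
  "joint_d3_a4_count",
  "joint_d3_a5_count",
  "joint_d3_a6_count",
  "joint_d4_a0_count",
  "joint_d4_a1_count",
  "joint_d4_a2_count",
  "joint_d4_a3_count",
  "joint_d4_a4_count",
  "joint_d4_a5_count",
  "joint_d4_a6_count",
  "joint_d5_a0_count",
  "joint_d5_a1_count",
  "joint_d5_a2_count",
  "joint_d5_a3_count",
  "joint_d5_a4_count",
  "joint_d5_a5_count",
  "joint_d5_a6_count",
  "joint_d6_a0_count",
  "joint_d6_a1_count",
  "joint_d6_a2_count",
  "joint_d6_a3_count",
  "joint_d6_a4_count",
  "joint_d6_a5_count",
  "joint_d6_a6_count",
  "joint_d0_a0_area_total",
  "joint_d0_a1_area_total",
  "joint_d0_a2_area_total",
  "joint_d0_a3_area_total",
  "joint_d0_a4_area_total",
  "joint_d0_a5_area_total",
  "joint_d0_a6_area_total",
  "joint_d1_a0_area_total",
  "joint_d1_a1_area_total",
  "joint_d1_a2_area_total",
  "joint_d1_a3_area_total",
  "joint_d1_a4_area_total",
  "joint_d1_a5_area_total",
  "joint_d1_a6_area_total",
  "joint_d2_a0_area_total",
  "joint_d2_a1_area_total",
  "joint_d2_a2_area_total",
  "joint_d2_a3_area_total",
  "joint_d2_a4_area_total",
  "joint_d2_a5_area_total",
  "joint_d2_a6_area_total",
  "joint_d3_a0_area_total",
  "joint_d3_a1_area_total",
  "joint_d3_a2_area_total",
  "joint_d3_a3_area_total",
  "joint_d3_a4_area_total",
  "joint_d3_a5_area_total",
  "joint_d3_a6_area_total",
  "joint_d4_a0_area_total",
  "joint_d4_a1_area_total",
  "joint_d4_a2_area_total",
  "joint_d4_a3_area_total",
  "joint_d4_a4_area_total",
  "joint_d4_a5_area_total",
  "joint_d4_a6_area_total",
  "joint_d5_a0_area_total",
  "joint_d5_a1_area_total",
  "joint_d5_a2_area_total",
  "joint_d5_a3_area_total",
  "joint_d5_a4_area_total",
  "joint_d5_a5_area_total",
  "joint_d5_a6_area_total",
  "joint_d6_a0_area_total",
  "joint_d6_a1_area_total",
  "joint_d6_a2_area_total",
  "joint_d6_a3_area_total",
  "joint_d6_a4_area_total",
  "joint_d6_a5_area_total",
  "joint_d6_a6_area_total",
  "tumor_area_total_mm2",
  "tumor_area_mean_per_slide_mm2"
 ]
}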