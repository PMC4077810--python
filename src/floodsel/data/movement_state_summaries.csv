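buffalo_id,dist_rest_mean,dist_rest_sd,dist_graze_mean,dist_graze_sd,dist_walk_mean,dist_walk_sd,dist_relocate_mean,dist_relocate_sd,angle_rest_mean,angle_rest_sd,angle_graze_mean,angle_graze_sd,angle_walk_mean,angle_walk_sd,angle_relocate_mean,angle_relocate_sd
B3,22,14,190,93,559,141,1266,365,96,53,61,48,53,45,43,42
B4,22,14,200,101,629,177,1709,540,97,53,67,50,54,46,46,48
B5,31,22,258,109,689,177,1700,576,96,53,67,50,54,45,42,41
B6,25,18,233,113,709,206,1966,528,95,55,61,48,50,44,40,32
B7,20,13,208,106,636,169,1560,646,99,54,71,51,57,45,43,38
B8,31,25,272,108,679,155,1453,443,94,55,58,46,51,42,47,43
B9,22,16,247,125,760,203,1933,644,97,53,65,50,53,45,42,41
B10,19,13,194,107,666,216,2263,588,104,53,76,53,59,49,21,28
B11,16,9,204,122,692,196,1702,516,99,53,63,50,48,42,35,37
B12,18,13,210,98,579,134,1215,396,95,54,59,47,50,42,42,39
B13,14,8,173,108,623,172,1535,490,99,53,68,51,51,43,48,42
B14,24,17,256,123,725,188,1761,566,94,53,58,47,47,41,43,39
B15,33,26,269,114,741,194,1912,660,97,54,63,48,57,48,41,43
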