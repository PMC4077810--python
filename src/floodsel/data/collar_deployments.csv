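buffalo_id,season,year,mdt_m,time_threshold_h,n_fixes
B1,rainy,2008,60,8,1845
B2,rainy,2008,80,10,1028
B3,early_flood,2008,50,10,1803
B3,late_flood,2008,50,10,1995
B3,rainy,2009,50,8,1230
B4,early_flood,2008,70,10,1804
B4,late_flood,2008,70,10,1774
B4,rainy,2008,70,10,1282
B5,early_flood,2008,90,10,1921
B5,late_flood,2008,90,10,1967
B5,rainy,2009,90,5,1754
B6,early_flood,2008,60,10,1751
B6,late_flood,2008,60,10,1793
B6,rainy,2008,60,10,1400
B7,early_flood,2009,50,10,1913
B7,late_flood,2008,50,10,701
B7,rainy,2009,50,9,1774
B8,early_flood,2009,100,10,1884
B8,late_flood,2008,100,6,653
B8,rainy,2009,100,5,1718
B9,early_flood,2009,70,5,410
B9,late_flood,2009,70,10,1917
B9,rainy,2010,70,5,1858
B10,early_flood,2009,50,10,430
B10,late_flood,2009,50,9,1174
B11,late_flood,2009,60,10,2147
B11,rainy,2010,60,7,1922
B12,early_flood,2009,40,10,462
B12,late_flood,2009,40,10,2108
B12,rainy,2010,40,4,719
B13,early_flood,2010,40,10,1285
B13,late_flood,2009,40,10,1756
B13,rainy,2010,40,4,1827
B14,late_flood,2009,70,4,640
B14,rainy,2010,70,6,819
B15,early_flood,2010,100,10,1500
B15,late_flood,2009,100,5,563
B15,rainy,2010,100,9,1481
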