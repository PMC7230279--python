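equation,sex,age_lo,age_hi,intercept,w_coef,h_coef,h_unit,a_coef,source_note
harris_benedict,M,0,18,66.473,13.7516,5.0033,cm,-6.755,Harris-Benedict 1919 adult male kcal/d applied unchanged to children
harris_benedict,F,0,18,655.0955,9.5634,1.8496,cm,-4.6756,Harris-Benedict 1919 adult female kcal/d applied unchanged to children
who,M,0,3,-54,60.9,0.0,cm,0.0,FAO/WHO/UNU 1985 weight-only published in kcal/d
who,M,3,10,495,22.7,0.0,cm,0.0,FAO/WHO/UNU 1985 weight-only published in kcal/d
who,M,10,18,651,17.5,0.0,cm,0.0,FAO/WHO/UNU 1985 weight-only published in kcal/d
who,F,0,3,-51,61.0,0.0,cm,0.0,FAO/WHO/UNU 1985 weight-only published in kcal/d
who,F,3,10,499,22.5,0.0,cm,0.0,FAO/WHO/UNU 1985 weight-only published in kcal/d
who,F,10,18,746,12.2,0.0,cm,0.0,FAO/WHO/UNU 1985 weight-only published in kcal/d
schofield_w,M,0,3,-30.353762,59.512494,0.0,cm,0.0,Schofield 1985 weight-only MJ/d x 239.006
schofield_w,M,3,10,504.30266,22.70557,0.0,cm,0.0,Schofield 1985 weight-only MJ/d x 239.006
schofield_w,M,10,18,658.222524,17.686444,0.0,cm,0.0,Schofield 1985 weight-only MJ/d x 239.006
schofield_w,F,0,3,-31.07078,58.317464,0.0,cm,0.0,Schofield 1985 weight-only MJ/d x 239.006
schofield_w,F,3,10,485.899198,20.31551,0.0,cm,0.0,Schofield 1985 weight-only MJ/d x 239.006
schofield_w,F,10,18,692.639388,13.384336,0.0,cm,0.0,Schofield 1985 weight-only MJ/d x 239.006
schofield_wh,M,0,3,-617.591504,0.167304,1517.449094,m,0.0,Schofield 1985 weight+height (H in m) MJ/d x 239.006
schofield_wh,M,3,10,414.914416,19.598492,130.25827,m,0.0,Schofield 1985 weight+height (H in m) MJ/d x 239.006
schofield_wh,M,10,18,515.535942,16.252408,137.189444,m,0.0,Schofield 1985 weight+height (H in m) MJ/d x 239.006
schofield_wh,F,0,3,-413.48038,16.252408,1023.184686,m,0.0,Schofield 1985 weight+height (H in m) MJ/d x 239.006
schofield_wh,F,3,10,371.176318,16.969426,161.807062,m,0.0,Schofield 1985 weight+height (H in m) MJ/d x 239.006
schofield_wh,F,10,18,200.048022,8.36521,465.583688,m,0.0,Schofield 1985 weight+height (H in m) MJ/d x 239.006
oxford,M,0,3,-33.699846,60.94653,0.0,cm,0.0,Henry 2005 Oxford weight-only MJ/d x 239.006
oxford,M,3,10,513.8629,22.394862,0.0,cm,0.0,Henry 2005 Oxford weight-only MJ/d x 239.006
oxford,M,10,18,580.78458,18.379561,0.0,cm,0.0,Henry 2005 Oxford weight-only MJ/d x 239.006
oxford,F,0,3,-23.064079,58.795476,0.0,cm,0.0,Henry 2005 Oxford weight-only MJ/d x 239.006
oxford,F,3,10,506.69272,20.124305,0.0,cm,0.0,Henry 2005 Oxford weight-only MJ/d x 239.006
oxford,F,10,18,760.03908,11.113779,0.0,cm,0.0,Henry 2005 Oxford weight-only MJ/d x 239.006
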