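year,total,grid,random,pct_random,pct_boating,processed
2008,3892,3562,330,8,84,3792
2009,4067,3673,394,10,92,3989
2010,4051,3650,401,10,92,3966
2011,3947,3562,385,10,94,3846
2012,3920,3535,385,10,95,3849
2013,3981,3578,403,10,90,3839
2014,4216,3507,709,17,94,4176
2015,4219,3525,694,16,93,4137
2016,4278,3563,715,17,94,4168
2017,4231,3534,697,16,93,2831
2018,4233,3531,702,17,93,2274
2019,4270,3555,715,17,94,4203
2020,2399,1704,695,29,94,2366
2021,4471,3733,738,17,94,4415
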