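# Synthetic stand-in for the annual hatchlings-released table
# (Tamaulipas index beaches, 1966-2018).  Not observed data: a
# saturating (logistic) trend with lognormal noise, asymptoting over
# the final decade as the real release series does.
year,hatchlings
1966,1442
1967,1945
1968,1541
1969,2469
1970,2731
1971,3618
1972,4314
1973,4538
1974,5512
1975,6661
1976,7623
1977,8372
1978,11059
1979,14005
1980,15269
1981,19210
1982,21944
1983,25363
1984,32274
1985,35445
1986,48425
1987,54175
1988,68283
1989,72128
1990,84099
1991,99843
1992,114746
1993,146562
1994,127152
1995,175118
1996,186361
1997,211414
1998,214825
1999,288898
2000,303978
2001,330477
2002,404267
2003,388863
2004,440613
2005,393930
2006,436611
2007,414930
2008,433275
2009,475733
2010,511689
2011,459332
2012,580747
2013,592397
2014,620915
2015,593839
2016,551679
2017,535223
2018,650859
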