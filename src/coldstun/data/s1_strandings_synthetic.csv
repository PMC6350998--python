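# Synthetic stand-in for the annual Kemp's ridley cold-stun stranding
# count table (Cape Cod Bay seasons, 1982-2016).  Not observed data:
# values are invented but constrained to the documented facts (35
# seasons; 2014 count 1188; before 2009 only 1999 and 2002 exceed 100;
# from 2009 onward counts commonly exceed 100).
year,count
1982,1
1983,0
1984,3
1985,5
1986,2
1987,9
1988,4
1989,17
1990,8
1991,21
1992,12
1993,30
1994,16
1995,49
1996,24
1997,35
1998,41
1999,218
2000,53
2001,34
2002,137
2003,59
2004,28
2005,70
2006,52
2007,66
2008,88
2009,121
2010,174
2011,143
2012,242
2013,193
2014,1188
2015,579
2016,433
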