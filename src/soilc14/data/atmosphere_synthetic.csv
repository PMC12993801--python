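# synthetic bomb-curve fixture: baseline -5 permil, linear rise 1955-1964,
# peak +700 permil in 1964, exponential relaxation tau=16 yr
year,delta14c_permil
1900,-5.0
1901,-5.0
1902,-5.0
1903,-5.0
1904,-5.0
1905,-5.0
1906,-5.0
1907,-5.0
1908,-5.0
1909,-5.0
1910,-5.0
1911,-5.0
1912,-5.0
1913,-5.0
1914,-5.0
1915,-5.0
1916,-5.0
1917,-5.0
1918,-5.0
1919,-5.0
1920,-5.0
1921,-5.0
1922,-5.0
1923,-5.0
1924,-5.0
1925,-5.0
1926,-5.0
1927,-5.0
1928,-5.0
1929,-5.0
1930,-5.0
1931,-5.0
1932,-5.0
1933,-5.0
1934,-5.0
1935,-5.0
1936,-5.0
1937,-5.0
1938,-5.0
1939,-5.0
1940,-5.0
1941,-5.0
1942,-5.0
1943,-5.0
1944,-5.0
1945,-5.0
1946,-5.0
1947,-5.0
1948,-5.0
1949,-5.0
1950,-5.0
1951,-5.0
1952,-5.0
1953,-5.0
1954,-5.0
1955,-5.0
1956,73.3333
1957,151.6667
1958,230.0
1959,308.3333
1960,386.6667
1961,465.0
1962,543.3333
1963,621.6667
1964,700.0
1965,657.2862
1966,617.1603
1967,579.4655
1968,544.0546
1969,510.789
1970,479.5389
1971,450.1822
1972,422.6041
1973,396.6969
1974,372.3593
1975,349.4963
1976,328.0184
1977,307.8419
1978,288.8877
1979,271.082
1980,254.355
1981,238.6415
1982,223.88
1983,210.0129
1984,196.9859
1985,184.7482
1986,173.2519
1987,162.4522
1988,152.3068
1989,142.776
1990,133.8227
1991,125.4119
1992,117.5106
1993,110.0881
1994,103.1153
1995,96.5649
1996,90.4114
1997,84.6307
1998,79.2002
1999,74.0988
2000,69.3065
2001,64.8045
2002,60.5752
2003,56.6022
2004,52.8699
2005,49.3638
2006,46.07
2007,42.9759
2008,40.0691
2009,37.3385
2010,34.7734
2011,32.3636
2012,30.0999
2013,27.9733
2014,25.9755
2015,24.0988
2016,22.3358
2017,20.6796
2018,19.1238
2019,17.6622
2020,16.2892
2021,14.9993
2022,13.7876
2023,12.6493
2024,11.58
2025,10.5755
2026,9.6318
2027,8.7453
2028,7.9125
2029,7.1302
2030,6.3953
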