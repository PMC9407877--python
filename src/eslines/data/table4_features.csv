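year,pair,feature,value
2000,NPP_SC,threshold_x,3.75
2000,NPP_SC,threshold_y,1386.35
2000,NPP_WY,threshold_x,3.54
2000,NPP_WY,threshold_y,1379.62
2000,WY_SC,threshold_x,554.12
2000,WY_SC,threshold_y,1183.14
2000,WY_FP,threshold_x,587.20
2000,WY_FP,threshold_y,5.91
2000,NPP_FP,threshold_x,6.00
2000,NPP_FP,threshold_y,6.13
2000,SC_FP,k,0.9995
2000,SC_FP,b,6.53
2001,NPP_SC,threshold_x,4.68
2001,NPP_SC,threshold_y,1517.80
2001,NPP_WY,threshold_x,4.12
2001,NPP_WY,threshold_y,803.00
2001,WY_SC,threshold_x,460.27
2001,WY_SC,threshold_y,1611.79
2001,WY_FP,threshold_x,367.30
2001,WY_FP,threshold_y,5.72
2001,NPP_FP,threshold_x,5.40
2001,NPP_FP,threshold_y,5.64
2001,SC_FP,k,0.9997
2001,SC_FP,b,5.60
2002,NPP_SC,threshold_x,4.29
2002,NPP_SC,threshold_y,332.45
2002,NPP_WY,threshold_x,3.96
2002,NPP_WY,threshold_y,978.35
2002,WY_SC,threshold_x,300.01
2002,WY_SC,threshold_y,338.98
2002,WY_FP,threshold_x,424.20
2002,WY_FP,threshold_y,5.50
2002,NPP_FP,threshold_x,6.50
2002,NPP_FP,threshold_y,5.54
2002,SC_FP,k,0.9991
2002,SC_FP,b,6.02
2003,NPP_SC,threshold_x,5.19
2003,NPP_SC,threshold_y,1306.24
2003,NPP_WY,threshold_x,3.49
2003,NPP_WY,threshold_y,1439.64
2003,WY_SC,threshold_x,1021.36
2003,WY_SC,threshold_y,1296.03
2003,WY_FP,threshold_x,884.70
2003,WY_FP,threshold_y,5.25
2003,NPP_FP,threshold_x,9.50
2003,NPP_FP,threshold_y,5.64
2003,SC_FP,k,0.9997
2003,SC_FP,b,5.62
2004,NPP_SC,threshold_x,7.45
2004,NPP_SC,threshold_y,3254.79
2004,NPP_WY,threshold_x,2.88
2004,NPP_WY,threshold_y,1100.41
2004,WY_SC,threshold_x,1038.03
2004,WY_SC,threshold_y,4006.01
2004,WY_FP,threshold_x,402.50
2004,WY_FP,threshold_y,5.91
2004,NPP_FP,threshold_x,5.40
2004,NPP_FP,threshold_y,5.96
2004,SC_FP,k,0.9998
2004,SC_FP,b,5.64
2005,NPP_SC,threshold_x,4.88
2005,NPP_SC,threshold_y,1139.83
2005,NPP_WY,threshold_x,4.04
2005,NPP_WY,threshold_y,1146.43
2005,WY_SC,threshold_x,761.87
2005,WY_SC,threshold_y,1197.49
2005,WY_FP,threshold_x,684.80
2005,WY_FP,threshold_y,6.02
2005,NPP_FP,threshold_x,8.60
2005,NPP_FP,threshold_y,6.06
2005,SC_FP,k,0.9997
2005,SC_FP,b,6.34
2006,NPP_SC,threshold_x,4.69
2006,NPP_SC,threshold_y,725.93
2006,NPP_WY,threshold_x,4.06
2006,NPP_WY,threshold_y,954.79
2006,WY_SC,threshold_x,321.33
2006,WY_SC,threshold_y,695.95
2006,WY_FP,threshold_x,486.40
2006,WY_FP,threshold_y,6.72
2006,NPP_FP,threshold_x,4.70
2006,NPP_FP,threshold_y,6.53
2006,SC_FP,k,0.9995
2006,SC_FP,b,6.80
2007,NPP_SC,threshold_x,4.53
2007,NPP_SC,threshold_y,1212.90
2007,NPP_WY,threshold_x,4.00
2007,NPP_WY,threshold_y,1218.52
2007,WY_SC,threshold_x,784.28
2007,WY_SC,threshold_y,1301.24
2007,WY_FP,threshold_x,555.80
2007,WY_FP,threshold_y,6.93
2007,NPP_FP,threshold_x,6.40
2007,NPP_FP,threshold_y,6.59
2007,SC_FP,k,0.9997
2007,SC_FP,b,6.95
2008,NPP_SC,threshold_x,4.31
2008,NPP_SC,threshold_y,1510.45
2008,NPP_WY,threshold_x,4.56
2008,NPP_WY,threshold_y,962.81
2008,WY_SC,threshold_x,652.23
2008,WY_SC,threshold_y,1669.39
2008,WY_FP,threshold_x,614.10
2008,WY_FP,threshold_y,7.37
2008,NPP_FP,threshold_x,5.40
2008,NPP_FP,threshold_y,7.29
2008,SC_FP,k,0.9997
2008,SC_FP,b,7.18
2009,NPP_SC,threshold_x,5.25
2009,NPP_SC,threshold_y,945.13
2009,NPP_WY,threshold_x,4.61
2009,NPP_WY,threshold_y,772.81
2009,WY_SC,threshold_x,418.19
2009,WY_SC,threshold_y,884.83
2009,WY_FP,threshold_x,470.10
2009,WY_FP,threshold_y,7.14
2009,NPP_FP,threshold_x,6.30
2009,NPP_FP,threshold_y,7.11
2009,SC_FP,k,0.9996
2009,SC_FP,b,7.28
2010,NPP_SC,threshold_x,3.99
2010,NPP_SC,threshold_y,1627.28
2010,NPP_WY,threshold_x,4.77
2010,NPP_WY,threshold_y,781.59
2010,WY_SC,threshold_x,468.34
2010,WY_SC,threshold_y,1572.66
2010,WY_FP,threshold_x,453.30
2010,WY_FP,threshold_y,7.27
2010,NPP_FP,threshold_x,5.50
2010,NPP_FP,threshold_y,7.15
2010,SC_FP,k,0.9997
2010,SC_FP,b,7.09
2011,NPP_SC,threshold_x,3.61
2011,NPP_SC,threshold_y,1033.68
2011,NPP_WY,threshold_x,4.75
2011,NPP_WY,threshold_y,927.59
2011,WY_SC,threshold_x,582.29
2011,WY_SC,threshold_y,1066.09
2011,WY_FP,threshold_x,505.50
2011,WY_FP,threshold_y,7.73
2011,NPP_FP,threshold_x,5.30
2011,NPP_FP,threshold_y,7.61
2011,SC_FP,k,0.9996
2011,SC_FP,b,7.39
2012,NPP_SC,threshold_x,5.15
2012,NPP_SC,threshold_y,1975.39
2012,NPP_WY,threshold_x,4.68
2012,NPP_WY,threshold_y,916.55
2012,WY_SC,threshold_x,599.66
2012,WY_SC,threshold_y,2183.67
2012,WY_FP,threshold_x,517.50
2012,WY_FP,threshold_y,7.33
2012,NPP_FP,threshold_x,5.50
2012,NPP_FP,threshold_y,7.19
2012,SC_FP,k,0.9998
2012,SC_FP,b,7.11
2013,NPP_SC,threshold_x,5.61
2013,NPP_SC,threshold_y,1996.45
2013,NPP_WY,threshold_x,4.88
2013,NPP_WY,threshold_y,696.88
2013,WY_SC,threshold_x,473.73
2013,WY_SC,threshold_y,2257.91
2013,WY_FP,threshold_x,270.80
2013,WY_FP,threshold_y,8.29
2013,NPP_FP,threshold_x,5.60
2013,NPP_FP,threshold_y,8.09
2013,SC_FP,k,0.9998
2013,SC_FP,b,8.24
2014,NPP_SC,threshold_x,3.95
2014,NPP_SC,threshold_y,504.21
2014,NPP_WY,threshold_x,4.57
2014,NPP_WY,threshold_y,1025.30
2014,WY_SC,threshold_x,301.90
2014,WY_SC,threshold_y,478.84
2014,WY_FP,threshold_x,517.10
2014,WY_FP,threshold_y,7.81
2014,NPP_FP,threshold_x,6.60
2014,NPP_FP,threshold_y,7.74
2014,SC_FP,k,0.9993
2014,SC_FP,b,8.17
2015,NPP_SC,threshold_x,4.98
2015,NPP_SC,threshold_y,559.82
2015,NPP_WY,threshold_x,4.69
2015,NPP_WY,threshold_y,1006.75
2015,WY_SC,threshold_x,373.17
2015,WY_SC,threshold_y,527.14
2015,WY_FP,threshold_x,468.90
2015,WY_FP,threshold_y,8.24
2015,NPP_FP,threshold_x,7.60
2015,NPP_FP,threshold_y,8.25
2015,SC_FP,k,0.9993
2015,SC_FP,b,8.28
2016,NPP_SC,threshold_x,3.54
2016,NPP_SC,threshold_y,1202.79
2016,NPP_WY,threshold_x,4.76
2016,NPP_WY,threshold_y,1042.39
2016,WY_SC,threshold_x,183.32
2016,WY_SC,threshold_y,1173.02
2016,WY_FP,threshold_x,587.00
2016,WY_FP,threshold_y,8.25
2016,NPP_FP,threshold_x,6.20
2016,NPP_FP,threshold_y,8.21
2016,SC_FP,k,0.9995
2016,SC_FP,b,8.61
2017,NPP_SC,threshold_x,4.84
2017,NPP_SC,threshold_y,893.33
2017,NPP_WY,threshold_x,5.73
2017,NPP_WY,threshold_y,1042.21
2017,WY_SC,threshold_x,259.75
2017,WY_SC,threshold_y,924.20
2017,WY_FP,threshold_x,525.70
2017,WY_FP,threshold_y,8.86
2017,NPP_FP,threshold_x,5.40
2017,NPP_FP,threshold_y,8.72
2017,SC_FP,k,0.9996
2017,SC_FP,b,8.82
2018,NPP_SC,threshold_x,4.66
2018,NPP_SC,threshold_y,1165.07
2018,NPP_WY,threshold_x,6.08
2018,NPP_WY,threshold_y,1200.92
2018,WY_SC,threshold_x,191.20
2018,WY_SC,threshold_y,1039.53
2018,WY_FP,threshold_x,544.70
2018,WY_FP,threshold_y,9.49
2018,NPP_FP,threshold_x,5.40
2018,NPP_FP,threshold_y,9.27
2018,SC_FP,k,0.9995
2018,SC_FP,b,9.91
2019,NPP_SC,threshold_x,4.97
2019,NPP_SC,threshold_y,1795.86
2019,NPP_WY,threshold_x,5.98
2019,NPP_WY,threshold_y,693.92
2019,WY_SC,threshold_x,420.26
2019,WY_SC,threshold_y,1989.14
2019,WY_FP,threshold_x,286.70
2019,WY_FP,threshold_y,9.38
2019,NPP_FP,threshold_x,5.00
2019,NPP_FP,threshold_y,9.30
2019,SC_FP,k,0.9998
2019,SC_FP,b,8.72
2020,NPP_SC,threshold_x,5.06
2020,NPP_SC,threshold_y,1545.14
2020,NPP_WY,threshold_x,6.07
2020,NPP_WY,threshold_y,1194.82
2020,WY_SC,threshold_x,760.21
2020,WY_SC,threshold_y,1742.78
2020,WY_FP,threshold_x,594.80
2020,WY_FP,threshold_y,9.16
2020,NPP_FP,threshold_x,4.90
2020,NPP_FP,threshold_y,9.03
2020,SC_FP,k,0.9998
2020,SC_FP,b,9.01
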